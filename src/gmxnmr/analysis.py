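"""Superposition-free structural comparison.

The distance RMSD between two conformers is the root mean square
difference over all unordered atom pairs (i < j) of their internal
distances.  Because only internal distances enter, the metric is exactly
invariant under rigid motions and needs no least-squares superposition —
which avoids the RMSD jumps superposition can cause when structures
differ substantially.

When several experimental models are deposited, a simulation frame is
scored against the *closest* model (minimum over the ensemble): the
models are equally consistent with the data, so proximity to any one of
them counts.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .structures import Ensemble, StructureModel


def distance_rmsd(frame: StructureModel, reference: StructureModel,
                  atom_subset: Optional[Iterable[int]] = None,
                  stride: int = 1) -> float:
    """All-pairs distance RMSD [nm] between two conformers.

    ``atom_subset`` restricts the comparison (default: all atoms common to
    both).  ``stride`` subsamples the subset for very large chains; the
    default uses every atom.
    """
    if atom_subset is None:
        subset = sorted(set(frame.coordinates) & set(reference.coordinates))
    else:
        subset = sorted(atom_subset)
    subset = subset[::max(1, stride)]
    if len(subset) < 2:
        raise ValueError("distance RMSD needs at least two atoms")
    d_frame = pdist(frame.array(subset))
    d_ref = pdist(reference.array(subset))
    return float(np.sqrt(np.mean((d_frame - d_ref) ** 2)))


def min_model_rmsd(frame: StructureModel, ensemble: Ensemble,
                   atom_subset: Optional[Iterable[int]] = None,
                   stride: int = 1) -> float:
    """Distance RMSD [nm] to the closest model of the ensemble."""
    if not ensemble.models:
        raise ValueError("empty ensemble")
    subset = list(atom_subset) if atom_subset is not None else None
    return min(distance_rmsd(frame, model, subset, stride)
               for model in ensemble.models)


def rmsd_timeseries(frames: Sequence[StructureModel], ensemble: Ensemble,
                    atom_subset: Optional[Iterable[int]] = None,
                    dt: float = 1.0, stride: int = 1
                    ) -> list[tuple[float, float]]:
    """Min-over-models distance RMSD per frame, as (time, nm) pairs."""
    subset = list(atom_subset) if atom_subset is not None else None
    return [(k * dt, min_model_rmsd(frame, ensemble, subset, stride))
            for k, frame in enumerate(frames)]


def write_timeseries(series: Sequence[tuple[float, float]]) -> str:
    """Tab-separated (time, rmsd) text, plot-tool friendly."""
    lines = ["# time\trmsd_nm"]
    lines += [f"{t:g}\t{v:.6f}" for t, v in series]
    return "\n".join(lines) + "\n"
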