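"""In vacuo energy-minimization consistency check.

A cheap end-to-end sanity check of converted restraints: prepare the
deposited coordinates with the MD engine, minimize without solvent, and
measure how far the structure moved.  Correctly converted inputs should
stay within ~0.02 nm positional RMSD of the deposited model.

Requires the ``gmx`` binary on PATH; this module only orchestrates it.
"""
from __future__ import annotations

import shutil
import subprocess
from pathlib import Path

import numpy as np

_EM_MDP = """\
integrator  = steep
emtol       = 100.0
nsteps      = 500
cutoff-scheme = Verlet
pbc         = no
rlist       = 2.0
rcoulomb    = 2.0
rvdw        = 2.0
"""


class MinimizationError(RuntimeError):
    pass


def _run(cmd: list[str], cwd: Path) -> None:
    proc = subprocess.run(cmd, cwd=cwd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise MinimizationError(
            f"{' '.join(cmd)} failed:\n{proc.stderr[-2000:]}")


def positional_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least-squares superposed positional RMSD [same units as input]."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return float(np.sqrt(np.mean(np.sum((a @ rot.T - b) ** 2, axis=1))))


def minimized_rmsd(pdb_text: str, workdir: str | Path,
                   force_field: str = "amber99sb-ildn") -> float:
    """Minimize the first model in vacuo and return the positional RMSD [nm]
    between the input and minimized coordinates (heavy atoms, gmx required)."""
    if shutil.which("gmx") is None:
        raise MinimizationError("the 'gmx' binary is not on PATH")
    work = Path(workdir)
    work.mkdir(parents=True, exist_ok=True)
    (work / "input.pdb").write_text(pdb_text)
    (work / "em.mdp").write_text(_EM_MDP)
    _run(["gmx", "pdb2gmx", "-f", "input.pdb", "-o", "conf.gro", "-p", "topol.top",
          "-ff", force_field, "-water", "none", "-ignh"], work)
    _run(["gmx", "grompp", "-f", "em.mdp", "-c", "conf.gro", "-p", "topol.top",
          "-o", "em.tpr", "-maxwarn", "2"], work)
    _run(["gmx", "mdrun", "-deffnm", "em"], work)

    from .structures import read_gro

    start = read_gro(work / "conf.gro")
    end = read_gro(work / "em.gro")
    heavy = start.subset("heavy")
    return positional_rmsd(start.models[0].array(heavy),
                           end.models[0].array(heavy))
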