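"""Fluctuation and deviation statistics over conformational ensembles.

RMSD of a frame against a reference after least-squares (Kabsch)
superposition::

    RMSD = sqrt( sum_i m_i * |X_i - Y_i|^2 / M )

with m_i = 1 and M = N when unweighted.  RMSF of atom i over a frame
window::

    RMSF_i = sqrt( < |x_i - <x_i>|^2 > )

computed about the window-mean position after superposing all frames to
the window-mean structure (removes global rigid-body drift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import ComplexStructure, CoreRegionMap, Trajectory
from .exceptions import SuperpositionError, ValidationError


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------


def resolve_selection(structure: ComplexStructure,
                      selection: str | np.ndarray | None) -> np.ndarray:
    """Resolve a selection to flat atom indices.

    Accepts ``None`` (all atoms), an integer index array, or a string of
    comma-separated clauses: ``chain:<id>`` and/or ``ca``
    (e.g. ``"chain:A,ca"``).
    """
    if selection is None:
        return np.arange(structure.n_atoms)
    if not isinstance(selection, str):
        idx = np.asarray(selection, dtype=int)
        if idx.size == 0:
            raise ValidationError("selection resolves to zero atoms")
        return idx
    want_chain, want_ca = None, False
    for clause in selection.split(","):
        clause = clause.strip()
        if clause.startswith("chain:"):
            want_chain = clause.split(":", 1)[1]
        elif clause.lower() == "ca":
            want_ca = True
        elif clause:
            raise ValidationError(f"unknown selection clause {clause!r}")
    idx = [
        i
        for i, c, r, a in structure.iter_atoms()
        if (want_chain is None or c.chain_id == want_chain)
        and (not want_ca or a.name == "CA")
    ]
    if not idx:
        raise ValidationError(f"selection {selection!r} resolves to zero atoms")
    return np.asarray(idx, dtype=int)


def _selection_residues(structure: ComplexStructure,
                        indices: np.ndarray) -> list[tuple[str, int]]:
    flat = list(structure.iter_atoms())
    return [(flat[i][1].chain_id, flat[i][2].index) for i in indices]


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None):
    """Weighted least-squares rigid superposition of ``mobile`` onto
    ``reference``.

    Returns ``(rotation, translation, fitted)`` with
    ``fitted = mobile @ rotation.T + translation`` minimizing the
    weighted squared deviation.  The rotation is always proper
    (det = +1): a mirror image cannot be superposed exactly.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise SuperpositionError("coordinate sets must share shape (n, 3)")
    n = len(mobile)
    if n < 3:
        raise SuperpositionError("superposition needs at least 3 atoms")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise SuperpositionError("weights must be non-negative with positive sum")
    w = w / w.sum()
    cm = w @ mobile
    cr = w @ reference
    m0 = mobile - cm
    r0 = reference - cr
    h = (m0 * w[:, None]).T @ r0
    u, s, vt = np.linalg.svd(h)
    # rank-deficient (collinear) point sets leave the rotation ill-defined
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise SuperpositionError("degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    fitted = mobile @ rot.T + trans
    return rot, trans, fitted


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------


@dataclass
class RmsdSeries:
    values: np.ndarray  # per-frame RMSD, Angstrom
    frame_times: np.ndarray  # ns
    mass_weighted: bool
    selection: str


def _one_rmsd(x: np.ndarray, y: np.ndarray, m: np.ndarray) -> float:
    return float(np.sqrt(np.sum(m[:, None] * (x - y) ** 2) / m.sum()))


def rmsd_series(traj: Trajectory,
                reference: np.ndarray | int = 0,
                selection: str | np.ndarray | None = None,
                mass_weighted: bool = False,
                superpose: bool = True) -> RmsdSeries:
    """Per-frame RMSD versus a reference conformation.

    ``reference`` is a frame index or an explicit (n_sel, 3) coordinate
    array.  Each frame is first superposed onto the reference over the
    selection (skip with ``superpose=False``, e.g. for pre-aligned
    frames or selections of fewer than 3 atoms).  Mass-weighting uses
    the trajectory masses; with equal masses it equals the unweighted
    value exactly.
    """
    idx = resolve_selection(traj.reference, selection)
    sel_frames = traj.frames[:, idx, :]
    if isinstance(reference, (int, np.integer)):
        ref = sel_frames[int(reference)]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (len(idx), 3):
            raise ValidationError(
                f"reference must have shape ({len(idx)}, 3)"
            )
    masses = traj.masses[idx] if mass_weighted else np.ones(len(idx))
    fit_w = traj.masses[idx] if mass_weighted else None
    out = np.empty(traj.n_frames)
    for k, frame in enumerate(sel_frames):
        x = kabsch_superpose(frame, ref, fit_w)[2] if superpose else frame
        out[k] = _one_rmsd(x, ref, masses)
    return RmsdSeries(
        values=out,
        frame_times=traj.frame_times.copy(),
        mass_weighted=mass_weighted,
        selection=str(selection),
    )


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------


@dataclass
class RmsfResult:
    values: np.ndarray  # per-atom RMSF over the analysis selection, Angstrom
    atom_indices: np.ndarray  # flat indices into the reference structure
    residues: list[tuple[str, int]]  # (chain_id, residue_index) per atom
    selection: str
    frames_used: tuple[int, int]  # [first, last] frame indices, inclusive

    def by_residue(self, chain_id: str) -> dict[int, float]:
        """residue index -> RMSF for one chain (meaningful for Cα
        selections where each residue contributes one atom)."""
        return {
            res: float(v)
            for (cid, res), v in zip(self.residues, self.values)
            if cid == chain_id
        }


def rmsf(traj: Trajectory,
         selection: str | np.ndarray | None = None,
         frames: tuple[int, int] | None = None,
         fit_selection: str | np.ndarray | None = None) -> RmsfResult:
    """Per-atom positional fluctuation about the window-mean position.

    All frames in the window are superposed to the window-mean structure
    computed over ``fit_selection`` (default: all atoms, so the
    superposition frame does not depend on the analysis selection), then
    RMSF_i = sqrt(mean_t |x_i(t) - <x_i>|^2) is reported over
    ``selection``.
    """
    first, last = frames if frames is not None else (0, traj.n_frames - 1)
    if not (0 <= first <= last < traj.n_frames):
        raise ValidationError("frame window outside trajectory")
    if last - first + 1 < 2:
        raise ValidationError("RMSF needs at least 2 frames")
    window = traj.frames[first:last + 1]
    fit_idx = resolve_selection(traj.reference, fit_selection)

    # one alignment pass to frame 0, then a pass to the resulting mean
    aligned = np.empty_like(window)
    ref = window[0][fit_idx]
    for k, frame in enumerate(window):
        rot, trans, _ = kabsch_superpose(frame[fit_idx], ref)
        aligned[k] = frame @ rot.T + trans
    mean_structure = aligned.mean(axis=0)
    ref2 = mean_structure[fit_idx]
    for k, frame in enumerate(aligned):
        rot, trans, _ = kabsch_superpose(frame[fit_idx], ref2)
        aligned[k] = frame @ rot.T + trans
    mean_structure = aligned.mean(axis=0)

    dev2 = np.sum((aligned - mean_structure[None]) ** 2, axis=2)  # (T, n_atoms)
    all_rmsf = np.sqrt(dev2.mean(axis=0))
    idx = resolve_selection(traj.reference, selection)
    return RmsfResult(
        values=all_rmsf[idx],
        atom_indices=idx,
        residues=_selection_residues(traj.reference, idx),
        selection=str(selection),
        frames_used=(first, last),
    )


# ---------------------------------------------------------------------------
# Equilibration and region comparison
# ---------------------------------------------------------------------------


def equilibration_check(series: RmsdSeries,
                        window_ns: float = 10.0,
                        sd_tol: float = 0.3) -> float | None:
    """Earliest time t (ns) at which the RMSD standard deviation over
    [t, t + window_ns] drops to ``sd_tol`` or below; ``None`` if never."""
    t = series.frame_times
    span = t[-1] - t[0]
    if window_ns > span:
        raise ValidationError(
            f"window ({window_ns} ns) longer than the series ({span} ns)"
        )
    for k in range(len(t)):
        in_window = (t >= t[k]) & (t <= t[k] + window_ns)
        if t[k] + window_ns > t[-1]:
            break
        vals = series.values[in_window]
        if len(vals) >= 2 and np.std(vals, ddof=1) <= sd_tol:
            return float(t[k])
    return None


def region_rmsf_compare(rmsf_a: RmsfResult, rmsf_b: RmsfResult,
                        region_map: CoreRegionMap,
                        welch: bool = True):
    """Unpaired two-sided t-test of per-residue RMSF between two
    subunits, restricted to the structurally mapped residues.

    ``rmsf_a``/``rmsf_b`` should be Cα-per-residue results; the map's
    first column indexes subunit A residues and the second subunit B.
    Welch's unequal-variance variant by default (``welch=False`` for the
    pooled-variance Student test).  Returns (t, p, summaries).
    """
    lookup_a = {res: float(v) for (_, res), v in zip(rmsf_a.residues, rmsf_a.values)}
    lookup_b = {res: float(v) for (_, res), v in zip(rmsf_b.residues, rmsf_b.values)}
    covered = [(ra, rb) for ra, rb in region_map.pairs
               if ra in lookup_a and rb in lookup_b]
    sample_a = [lookup_a[ra] for ra, _ in covered]
    sample_b = [lookup_b[rb] for _, rb in covered]
    if not sample_a or not sample_b:
        raise ValidationError("region map covers no residues of both results")
    if len(sample_a) < 2 or len(sample_b) < 2:
        raise ValidationError("need at least 2 mapped residues per side")
    a = np.asarray(sample_a)
    b = np.asarray(sample_b)
    if np.allclose(a, b) and np.std(a) == 0 and np.std(b) == 0:
        t_stat, p_val = 0.0, 1.0  # degenerate identical-constant samples
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    summaries = {
        "a": {"n": len(a), "mean": float(a.mean()), "sd": float(a.std(ddof=1))},
        "b": {"n": len(b), "mean": float(b.mean()), "sd": float(b.std(ddof=1))},
        "welch": welch,
    }
    return t_stat, p_val, summaries
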