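"""Metric suite for comparing predicted and true contact maps.

* banded MAE/MSE — pixel errors restricted to the predicted genomic
  distance band (default 2 Mb) and coverage mask;
* SCC — a stratum-adjusted correlation in the spirit of HiCRep: a Pearson
  correlation is computed per diagonal stratum and the per-stratum values
  are combined with weights proportional to stratum length times the
  product of the two strata's standard deviations, yielding a value in
  [-1, 1] that equals 1 for identical maps;
* a reproducibility score in the spirit of GenomeDISCO: both maps are
  row-normalized to transition matrices, smoothed by random-walk powers
  ``t``, and 1 minus the L1 difference per non-empty node (averaged over
  ``t``) is returned — bounded above by 1 with equality for identical maps;
* a diamond insulation-score TAD boundary caller (a deliberately simple
  stand-in for the heavier published callers) and a one-to-one
  shift-tolerant Jaccard index for comparing boundary (or interaction) sets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .hicdata import ContactMap

__all__ = [
    "EvalReport",
    "banded_mae_mse",
    "scc",
    "disco_score",
    "insulation_boundaries",
    "boundary_jaccard",
    "evaluate_maps",
]


@dataclass
class EvalReport:
    chrom: str
    mae: float
    mse: float
    scc: float
    disco: float
    tad_jaccard: float
    max_distance_bp: int
    n_bins: int

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def to_tsv(self, path: str) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            fh.write("\t".join(d.keys()) + "\n")
            fh.write("\t".join(str(v) for v in d.values()) + "\n")


def _band_mask(N: int, bin_size: int, max_distance_bp: int) -> np.ndarray:
    idx = np.arange(N)
    return np.abs(idx[:, None] - idx[None, :]) * bin_size <= max_distance_bp


def banded_mae_mse(
    pred: ContactMap,
    truth: ContactMap,
    max_distance_bp: int = 2_000_000,
    mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """MAE and MSE over entries within the distance band (and coverage
    mask, when given)."""
    if pred.N != truth.N or pred.bin_size != truth.bin_size:
        raise ValueError("maps must share dimensions and bin size")
    sel = _band_mask(pred.N, pred.bin_size, max_distance_bp)
    if mask is not None:
        sel = sel & mask
    diff = pred.counts[sel] - truth.counts[sel]
    return float(np.abs(diff).mean()), float((diff**2).mean())


def scc(
    a: ContactMap,
    b: ContactMap,
    max_stratum: int | None = None,
    smooth_h: int = 0,
) -> float:
    """Stratum-adjusted correlation coefficient.

    Correlations are computed per diagonal (stratum) and averaged with
    weights ``n_d * sd_a(d) * sd_b(d)``; strata where either map is
    constant carry no information and are skipped with a warning.
    ``smooth_h > 0`` applies a mean filter of window ``2h + 1`` to both maps
    first (the smoothing idea of HiCRep).
    """
    if a.N != b.N:
        raise ValueError("maps must have equal dimensions")
    N = a.N
    if max_stratum is None:
        max_stratum = N - 1
    if max_stratum >= N:
        raise ValueError("max_stratum must be < N")
    A, B = a.counts, b.counts
    if smooth_h > 0:
        size = 2 * smooth_h + 1
        A = ndimage.uniform_filter(A, size=size, mode="constant")
        B = ndimage.uniform_filter(B, size=size, mode="constant")
    num = 0.0
    den = 0.0
    skipped = 0
    for d in range(0, max_stratum + 1):
        xa = np.diagonal(A, offset=d)
        xb = np.diagonal(B, offset=d)
        if len(xa) < 2:
            continue
        sa, sb = xa.std(), xb.std()
        if sa == 0 or sb == 0:
            skipped += 1
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        w = len(xa) * sa * sb
        num += w * r
        den += w
    if skipped:
        warnings.warn(f"scc: skipped {skipped} constant strata", stacklevel=2)
    if den == 0:
        raise ValueError("no informative strata: both maps are constant")
    return float(np.clip(num / den, -1.0, 1.0))


def disco_score(
    a: ContactMap, b: ContactMap, t_steps: tuple[int, ...] = (1, 2, 3)
) -> float:
    """Random-walk reproducibility score; 1 for identical maps, <= 1 always."""
    if a.N != b.N:
        raise ValueError("maps must have equal dimensions")

    def transition(cmap: ContactMap) -> tuple[np.ndarray, int]:
        C = cmap.counts
        s = C.sum(axis=1)
        if not (s > 0).any():
            raise ValueError("cannot score an all-zero map")
        P = np.divide(C, s[:, None], out=np.zeros_like(C), where=s[:, None] > 0)
        return P, int((s > 0).sum())

    Pa, na = transition(a)
    Pb, nb = transition(b)
    denom = 0.5 * (na + nb)
    scores = []
    Qa, Qb = np.eye(a.N), np.eye(b.N)
    for t in range(1, max(t_steps) + 1):
        Qa = Qa @ Pa
        Qb = Qb @ Pb
        if t in t_steps:
            diff = np.abs(Qa - Qb).sum() / denom
            scores.append(1.0 - diff)
    return float(np.mean(scores))


def insulation_boundaries(
    cmap: ContactMap,
    window: int = 10,
    min_separation: int = 5,
    z_threshold: float = 1.0,
) -> list[int]:
    """Call TAD boundaries as significant local minima of the diamond
    insulation profile.

    The insulation score of bin ``i`` is the mean contact count in the
    ``window x window`` diamond upstream-vs-downstream of ``i``.  Local
    minima whose z-score is below ``-z_threshold`` are called, and calls
    closer than ``min_separation`` keep only the deepest minimum.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    N = cmap.N
    if 2 * window + 1 >= N:
        raise ValueError(f"window {window} too large for {N} bins")
    C = cmap.counts
    prof = np.full(N, np.nan)
    for i in range(window, N - window):
        prof[i] = C[i - window : i, i + 1 : i + 1 + window].mean()
    valid = ~np.isnan(prof)
    vals = prof[valid]
    if vals.std() == 0:
        return []
    z = np.full(N, np.nan)
    z[valid] = (vals - vals.mean()) / vals.std()
    candidates = []
    for i in range(window + 1, N - window - 1):
        if np.isnan(prof[i]):
            continue
        if prof[i] <= prof[i - 1] and prof[i] <= prof[i + 1] and (
            prof[i] < prof[i - 1] or prof[i] < prof[i + 1]
        ):
            if z[i] <= -z_threshold:
                candidates.append(i)
    # enforce separation, keeping the deepest minimum of each cluster
    candidates.sort(key=lambda i: prof[i])
    chosen: list[int] = []
    for i in candidates:
        if all(abs(i - j) >= min_separation for j in chosen):
            chosen.append(i)
    return sorted(chosen)


def boundary_jaccard(set_a, set_b, tol: int = 5) -> float:
    """Shift-tolerant Jaccard index between two boundary sets.

    A one-to-one matching within ``tol`` bins defines the intersection; in
    one dimension a sorted greedy sweep yields a maximum matching.  Returns
    ``matched / (|A| + |B| - matched)`` in [0, 1]; 1 for two empty sets.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    a = sorted(set_a)
    b = sorted(set_b)
    if not a and not b:
        return 1.0
    matched = 0
    i = j = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= tol:
            matched += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return matched / (len(a) + len(b) - matched)


def evaluate_maps(
    pred: ContactMap,
    truth: ContactMap,
    max_distance_bp: int = 2_000_000,
    mask: np.ndarray | None = None,
    tad_window: int = 10,
    tad_tol: int = 5,
    max_stratum: int | None = None,
) -> EvalReport:
    """Full metric report for a predicted map against its ground truth."""
    if max_stratum is None:
        max_stratum = min(
            truth.N - 1, int(max_distance_bp // truth.bin_size)
        )
    mae, mse_val = banded_mae_mse(pred, truth, max_distance_bp, mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scc_val = scc(pred, truth, max_stratum=max_stratum)
    disco = disco_score(pred, truth)
    b_pred = insulation_boundaries(pred, window=tad_window)
    b_true = insulation_boundaries(truth, window=tad_window)
    jac = boundary_jaccard(b_pred, b_true, tol=tad_tol)
    return EvalReport(
        chrom=truth.chrom,
        mae=mae,
        mse=mse_val,
        scc=scc_val,
        disco=disco,
        tad_jaccard=jac,
        max_distance_bp=max_distance_bp,
        n_bins=truth.N,
    )
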