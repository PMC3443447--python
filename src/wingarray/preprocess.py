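"""Array quality control, normalization, and probe summarization.

Three stages, mirroring standard single-channel array practice:

1. :func:`qc_mask` — spatial QC.  Each subarray is tiled into windows; any
   window whose mean log2 intensity deviates from the array's typical level
   by more than ``z`` robust SDs is treated as a region of uneven
   hybridization and its probes are set to missing.  Arrays with a large
   masked fraction are flagged for rerun.
2. :func:`log2_loess_normalize` — log2 transform plus loess adjustment of
   each array against a reference pseudo-array (the probe-wise mean of all
   log2 arrays) in MA space.  Only transcript probes drive the fit; random
   control probes are transformed but carry no weight.
3. :func:`summarize_probes` — per-contig expression is the mean of the
   non-missing probes representing the contig.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datagen import RANDOM_CONTIG

META_COLUMNS = ["probe_id", "x", "y", "contig_id"]


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


@dataclass
class QCReport:
    """Per-array spatial QC summary."""

    window: int
    z_threshold: float
    max_masked_fraction: float
    arrays: dict[str, dict] = field(default_factory=dict)

    @property
    def flagged(self) -> list[str]:
        return [s for s, rec in self.arrays.items() if rec["flag"] == "rerun"]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _quantiles(values: np.ndarray) -> dict[str, float]:
    qs = np.nanquantile(values, [0.05, 0.25, 0.5, 0.75, 0.95])
    return {f"q{int(p * 100):02d}": float(v) for p, v in zip((0.05, 0.25, 0.5, 0.75, 0.95), qs)}


def qc_mask(
    raw: pd.DataFrame,
    window: int = 16,
    z_threshold: float = 4.0,
    max_masked_fraction: float = 0.25,
) -> tuple[pd.DataFrame, QCReport]:
    """Mask spatial regions of uneven intensity; flag heavily masked arrays.

    Probes falling in any ``window x window`` grid cell whose mean log2
    intensity deviates from the array median (of window means) by more than
    ``z_threshold`` robust SDs (1.4826 x MAD) are set to missing for that
    array.  Random control probes participate: artifacts are spatial, not
    biological.

    Returns the masked copy (missing = NaN) and a :class:`QCReport` with the
    per-array masked fraction, a pass/rerun flag, and intensity-distribution
    quantiles for all probes and for the random control probes.
    """
    x = raw["x"].to_numpy()
    y = raw["y"].to_numpy()
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > x.max() + 1 or window > y.max() + 1:
        raise ValueError(
            f"QC window {window} exceeds the probe grid "
            f"({x.max() + 1} x {y.max() + 1})"
        )
    win_id = (x // window) + 10_000_000 * (y // window)
    uniq, win_idx = np.unique(win_id, return_inverse=True)
    is_random = (raw["contig_id"] == RANDOM_CONTIG).to_numpy()

    masked = raw.copy()
    report = QCReport(window=window, z_threshold=z_threshold,
                      max_masked_fraction=max_masked_fraction)
    for col in sample_columns(raw):
        vals = raw[col].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logv = np.log2(vals)
        counts = np.bincount(win_idx, weights=np.isfinite(logv).astype(float),
                             minlength=len(uniq))
        sums = np.bincount(win_idx, weights=np.nan_to_num(logv), minlength=len(uniq))
        with np.errstate(invalid="ignore"):
            wmeans = sums / counts
        med = np.nanmedian(wmeans)
        mad = np.nanmedian(np.abs(wmeans - med))
        rsd = 1.4826 * mad
        deviant = np.abs(wmeans - med) > z_threshold * rsd
        bad = deviant[win_idx] & np.isfinite(logv)
        masked.loc[bad, col] = np.nan
        frac = float(bad.mean())
        report.arrays[col] = {
            "masked_fraction": frac,
            "flag": "rerun" if frac > max_masked_fraction else "pass",
            "log2_quantiles": _quantiles(logv),
            "random_probe_log2_quantiles": _quantiles(logv[is_random]) if is_random.any() else None,
        }
    return masked, report


def _hat_basis(a: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Piecewise-linear (hat-function) regression basis at points ``a``.

    Values outside the knot range are clamped to the boundary knot, giving
    flat extrapolation.
    """
    a = np.clip(a, knots[0], knots[-1])
    k = len(knots)
    right = np.clip(np.searchsorted(knots, a, side="right"), 1, k - 1)
    left = right - 1
    w = (a - knots[left]) / (knots[right] - knots[left])
    basis = np.zeros((a.size, k))
    rows = np.arange(a.size)
    basis[rows, left] = 1.0 - w
    basis[rows, right] = w
    return basis


def _loess_correction(m, a, fit_mask, span: float):
    """Fitted local-linear MA trend of M on A over ``fit_mask``.

    The trend is a least-squares fit of piecewise-linear hat functions on
    knots placed at abundance quantiles; the number of knots is set by the
    smoothing span (span 0.5 -> 20 knots over the abundance range).  Being
    an orthogonal projection, the smoother is exactly idempotent: one
    normalization pass reaches the fixed point and re-normalizing already
    normalized data is a numerical no-op, which iterated local regression
    with negative boundary weights does not guarantee.
    """
    af, mf = a[fit_mask], m[fit_mask]
    n_knots = min(int(np.ceil(10.0 / span)), max(4, af.size // 20))
    # Chebyshev-spaced quantile levels: extra knots near both abundance
    # extremes, where wide segments would otherwise leave boundary curvature
    levels = (1.0 - np.cos(np.pi * np.linspace(0.0, 1.0, n_knots))) / 2.0
    knots = np.unique(np.quantile(af, levels))
    if len(knots) < 2:  # all abundances identical: trend = plain mean
        return np.full(a.shape, mf.mean())
    H = _hat_basis(af, knots)
    beta, *_ = np.linalg.lstsq(H, mf, rcond=None)
    return _hat_basis(a, knots) @ beta


def log2_loess_normalize(
    masked: pd.DataFrame,
    span: float = 0.5,
    tol: float = 2e-4,
    max_iter: int = 20,
) -> pd.DataFrame:
    """Log2 transform and loess-normalize each array against the mean array.

    Iterates to the normalization fixed point: in each round, with reference
    R = probe-wise mean of all current log2 arrays, a degree-1 loess of
    M = log2(j) - R on the abundance covariate A = R is fit over the
    transcript probes of each array j and subtracted at every probe (random
    probes included); rounds repeat until the largest correction falls below
    ``tol``.  At the fixed point the residual MA trend of every array
    against the reference is ~0 and re-applying the function is a no-op to
    tolerance.

    The covariate is the reference log-intensity rather than the symmetric
    average (log2(j) + R) / 2: the symmetric form carries the array's own
    deviations in the x-variable, inducing a regression-to-the-mean slope
    that would reappear after every pass and destroy idempotency.

    Returns a table of the same shape whose sample columns hold normalized
    log2 values (missing values propagate).

    Raises
    ------
    ValueError
        If any present intensity is not strictly positive (reported with its
        probe id), or if an array has too few probes to fit.
    """
    cols = sample_columns(masked)
    if not cols:
        raise ValueError("no sample columns present")
    values = masked[cols].to_numpy(dtype=float)
    bad = np.nonzero(np.isfinite(values) & (values <= 0))
    if bad[0].size:
        pid = masked["probe_id"].iloc[bad[0][0]]
        raise ValueError(f"non-positive intensity for probe {pid!r}; cannot log2")

    log2v = np.log2(values)
    transcript = (masked["contig_id"] != RANDOM_CONTIG).to_numpy()
    for _ in range(max_iter):
        ref = np.nanmean(log2v, axis=1)
        worst = 0.0
        for j, col in enumerate(cols):
            m = log2v[:, j] - ref
            fit_mask = transcript & np.isfinite(m) & np.isfinite(ref)
            if fit_mask.sum() < 10:
                raise ValueError(f"array {col!r}: too few probes to fit loess")
            correction = _loess_correction(m, ref, fit_mask, span)
            correction = np.where(np.isfinite(ref) & np.isfinite(log2v[:, j]),
                                  correction, 0.0)
            log2v[:, j] -= correction
            worst = max(worst, float(np.abs(correction[fit_mask]).max()))
        if worst < tol:
            break
    out = masked.copy()
    out[cols] = log2v
    return out


def ma_trend(normalized: pd.DataFrame, span: float = 0.5, grid: int = 100) -> pd.DataFrame:
    """Refit the MA loess trend of each array vs the mean reference array.

    Diagnostic: evaluates the residual trend on a regular A-grid; after
    :func:`log2_loess_normalize` the absolute trend should be small
    everywhere.  Returns a DataFrame (grid points x arrays).
    """
    cols = sample_columns(normalized)
    values = normalized[cols].to_numpy(dtype=float)
    transcript = (normalized["contig_id"] != RANDOM_CONTIG).to_numpy()
    ref = np.nanmean(values, axis=1)
    trends = {}
    agrid = None
    for j, col in enumerate(cols):
        m = values[:, j] - ref
        a = ref
        ok = transcript & np.isfinite(m) & np.isfinite(a)
        af, mf = a[ok], m[ok]
        if agrid is None:
            agrid = np.linspace(np.quantile(af, 0.01), np.quantile(af, 0.99), grid)
        sm = lowess(mf, af, frac=span, it=0, delta=0.01 * (af.max() - af.min()),
                    return_sorted=True)
        trends[col] = np.interp(agrid, sm[:, 0], sm[:, 1])
    return pd.DataFrame(trends, index=agrid)


def summarize_probes(norm: pd.DataFrame, probemap: pd.Series | None = None) -> pd.DataFrame:
    """Summarize normalized probe values to one row per contig (probe mean).

    Random control probes are dropped.  A contig-sample cell is missing only
    if all of the contig's probes are missing in that sample.

    Parameters
    ----------
    norm
        Normalized (log2) probe table.
    probemap
        Optional probe_id -> contig_id Series; defaults to the table's own
        ``contig_id`` column.  Every transcript probe must be mapped.
    """
    transcript = norm[norm["contig_id"] != RANDOM_CONTIG]
    if probemap is not None:
        unmapped = ~transcript["probe_id"].isin(probemap.index)
        if unmapped.any():
            pid = transcript.loc[unmapped, "probe_id"].iloc[0]
            raise ValueError(f"probe {pid!r} has no contig in the probe map")
        contigs = transcript["probe_id"].map(probemap)
    else:
        contigs = transcript["contig_id"]
    cols = sample_columns(norm)
    expr = transcript[cols].groupby(contigs.to_numpy()).mean()
    expr.index.name = "contig_id"
    return expr
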