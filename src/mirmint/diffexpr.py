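"""Two-group differential expression with empirical-Bayes moderation.

The test statistic is a moderated t: per-feature residual variances are
shrunk toward a common prior whose scale and degrees of freedom are
estimated from the observed variance distribution by moment matching on
the log scale (scaled-F model). A no-shrinkage mode reduces exactly to
the ordinary pooled two-sample t and exists for oracle testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import special, stats

from .data_io import ExpressionMatrix, GROUP_NORMAL, GROUP_TUMOR, canonical_mirna_id
from .errors import DomainError, UsageError

logger = logging.getLogger("mirmint")


@dataclass
class DEResult:
    """Differential-expression summary for one feature (tumor vs normal)."""

    feature_id: str
    log_fc: float
    fold_change: float
    mean_tumor: float
    mean_normal: float
    t_stat: float
    p_value: float
    fdr: float
    direction: str | None  # "up"/"down" by sign of log_fc; None at exactly 0

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise DomainError(f"{self.feature_id}: fold_change must be positive")
        if not (0.0 <= self.p_value <= 1.0 and 0.0 <= self.fdr <= 1.0):
            raise DomainError(f"{self.feature_id}: p/fdr outside [0,1]")
        expected = "up" if self.log_fc > 0 else "down" if self.log_fc < 0 else None
        if self.direction != expected:
            raise DomainError(
                f"{self.feature_id}: direction {self.direction!r} inconsistent "
                f"with log_fc {self.log_fc}"
            )


@dataclass
class DEThresholds:
    """Selection cut-offs: symmetric linear fold-change, raw P and FDR.

    ``min_fold_change`` is applied symmetrically on the linear scale
    (keep if fold_change > fc or < 1/fc); ``None`` disables the
    fold-change cut (the mRNA cohorts use P and FDR only).
    """

    min_fold_change: float | None = 4.0
    max_p: float = 0.01
    max_fdr: float = 0.01

    def __post_init__(self) -> None:
        if self.min_fold_change is not None and not self.min_fold_change > 1:
            raise DomainError("min_fold_change must exceed 1")
        if not (0 < self.max_p <= 1 and 0 < self.max_fdr <= 1):
            raise DomainError("max_p and max_fdr must lie in (0,1]")

    def passes(self, r: DEResult) -> bool:
        fc_ok = self.min_fold_change is None or (
            r.fold_change > self.min_fold_change
            or r.fold_change < 1.0 / self.min_fold_change
        )
        return fc_ok and r.p_value < self.max_p and r.fdr < self.max_fdr


def log_transform(matrix: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Return a log2-scale copy of a linear-scale matrix.

    Guards against double transformation: a matrix already on the log2
    scale is refused.
    """
    if matrix.scale != "linear":
        raise UsageError("matrix is already log2-scaled; refusing to transform again")
    shifted = matrix.values + offset
    with np.errstate(invalid="ignore"):
        bad = np.nan_to_num(shifted, nan=1.0) <= 0
    if bad.any():
        i = int(np.argwhere(bad)[0][0])
        raise DomainError(
            f"nonpositive value for feature {matrix.feature_ids[i]!r} "
            f"with offset {offset}"
        )
    out = matrix.copy()
    out.values = np.log2(shifted)
    out.scale = "log2"
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DomainError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (prior_df, prior_var) from per-feature sample variances.

    Models s2 ~ prior_var * F(df, prior_df) and matches the first two
    moments of log(s2). Returns prior_df = inf when the observed spread
    is no larger than expected from chi-square sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    with np.errstate(divide="ignore"):
        z = np.log(s2)
    z = z[np.isfinite(z)]
    if z.size < 2:
        return np.inf, float(np.exp(z.mean())) if z.size else 1.0
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    prior_df = 2.0 * _trigamma_inverse(e_var)
    prior_var = float(
        np.exp(e_mean + special.digamma(prior_df / 2.0) - np.log(prior_df / 2.0))
    )
    return prior_df, prior_var


def moderate_variances(
    s2: np.ndarray, df: float, prior_df: float, prior_var: float
) -> np.ndarray:
    """Posterior (shrunk) variances under the scaled-F prior."""
    if np.isinf(prior_df):
        return np.full_like(np.asarray(s2, dtype=float), prior_var)
    return (df * np.asarray(s2, dtype=float) + prior_df * prior_var) / (df + prior_df)


def moderated_t_test(
    matrix: ExpressionMatrix,
    prior_df_mode: str | float = "moment",
) -> list[DEResult]:
    """Per-feature moderated two-group t-test (tumor vs normal).

    ``prior_df_mode``: ``"moment"`` estimates the variance prior from the
    data; ``"none"`` disables shrinkage (ordinary pooled t); a float
    forces that prior df (prior variance still moment-matched).
    """
    if matrix.scale != "log2":
        raise UsageError("moderated_t_test expects a log2-scale matrix")
    mask_t = matrix.group_mask(GROUP_TUMOR)
    mask_n = matrix.group_mask(GROUP_NORMAL)
    n1, n2 = int(mask_t.sum()), int(mask_n.sum())
    if n1 == 0 or n2 == 0:
        raise UsageError("each group needs at least one sample")
    if n1 < 2 or n2 < 2:
        warnings.warn(
            "a group has a single sample; variance pooled from the other group",
            stacklevel=2,
        )
    tumor = matrix.values[:, mask_t]
    normal = matrix.values[:, mask_n]
    mean_t = tumor.mean(axis=1)
    mean_n = normal.mean(axis=1)
    log_fc = mean_t - mean_n

    ss_t = ((tumor - mean_t[:, None]) ** 2).sum(axis=1) if n1 > 1 else np.zeros_like(mean_t)
    ss_n = ((normal - mean_n[:, None]) ** 2).sum(axis=1) if n2 > 1 else np.zeros_like(mean_n)
    df = (n1 - 1) + (n2 - 1)
    if df == 0:
        raise UsageError("no residual degrees of freedom (1 vs 1 design)")
    s2 = (ss_t + ss_n) / df
    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)

    if prior_df_mode == "none":
        prior_df = 0.0
        s2_post = s2
        df_total = float(df)
    else:
        if prior_df_mode == "moment":
            prior_df, prior_var = fit_variance_prior(s2, df)
        else:
            prior_df = float(prior_df_mode)
            _, prior_var = fit_variance_prior(s2, df)
        s2_post = moderate_variances(s2, df, prior_df, prior_var)
        df_total = df + prior_df

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = log_fc / (np.sqrt(s2_post) * se_factor)
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    p = np.clip(p, 0.0, 1.0)
    fdr = bh_adjust(p)

    results = []
    for i, fid in enumerate(matrix.feature_ids):
        lf = float(log_fc[i])
        results.append(
            DEResult(
                feature_id=fid,
                log_fc=lf,
                fold_change=float(2.0 ** lf),
                mean_tumor=float(mean_t[i]),
                mean_normal=float(mean_n[i]),
                t_stat=float(t_stat[i]),
                p_value=float(p[i]),
                fdr=float(fdr[i]),
                direction="up" if lf > 0 else "down" if lf < 0 else None,
            )
        )
    return results


def apply_thresholds(
    results: Sequence[DEResult],
    thresholds: DEThresholds,
    blacklist: Iterable[str] = (),
) -> list[DEResult]:
    """Filter DE results by the configured cut-offs and a blacklist.

    Output is sorted by FDR ascending, ties broken by |log_fc|
    descending then feature id. miRNA-style ids in the blacklist are
    matched case-insensitively on the ``hsa-`` convention.
    """
    if not results:
        raise UsageError("apply_thresholds requires a non-empty result list")
    black = {canonical_mirna_id(b) for b in blacklist}
    kept = [
        r
        for r in results
        if thresholds.passes(r) and canonical_mirna_id(r.feature_id) not in black
    ]
    kept.sort(key=lambda r: (r.fdr, -abs(r.log_fc), r.feature_id))
    return kept


# ---------------------------------------------------------------------------
# TSV round trip for DE tables
# ---------------------------------------------------------------------------

_DE_COLUMNS = [
    "feature_id",
    "log_fc",
    "fold_change",
    "mean_tumor",
    "mean_normal",
    "t_stat",
    "p_value",
    "fdr",
    "direction",
]


def write_de_table(results: Sequence[DEResult], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_DE_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.feature_id,
                        format(r.log_fc, ".10g"),
                        format(r.fold_change, ".10g"),
                        format(r.mean_tumor, ".10g"),
                        format(r.mean_normal, ".10g"),
                        format(r.t_stat, ".10g"),
                        format(r.p_value, ".10g"),
                        format(r.fdr, ".10g"),
                        r.direction or "none",
                    ]
                )
                + "\n"
            )


def read_de_table(path: str | Path) -> list[DEResult]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != _DE_COLUMNS:
        raise UsageError(f"{path}: not a DE table (bad header)")
    results = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        f = ln.split("\t")
        results.append(
            DEResult(
                feature_id=f[0],
                log_fc=float(f[1]),
                fold_change=float(f[2]),
                mean_tumor=float(f[3]),
                mean_normal=float(f[4]),
                t_stat=float(f[5]),
                p_value=float(f[6]),
                fdr=float(f[7]),
                direction=None if f[8] == "none" else f[8],
            )
        )
    return results
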