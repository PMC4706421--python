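"""Validation statistics: Pearson correlations and ROC/AUC.

The continuous scores are validated two ways, mirroring standard practice
for composite cardiometabolic scores:

* **agreement** — Pearson product–moment correlation between the siMS
  score and each cohort-fitted comparator score, optionally after log
  transform of skewed columns, with pairwise complete-case deletion;
* **discrimination** — area under the ROC curve using the dichotomous
  metabolic-syndrome classification as the state variable.  The AUC is
  computed by the Mann–Whitney construction with midrank tie handling
  (AUC = U / (n_pos * n_neg)); the 95% confidence interval uses the
  Hanley–McNeil standard-error formula with a normal approximation,
  truncated to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ScoreTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float
    log_x: bool = False
    log_y: bool = False

    def __post_init__(self):
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if self.n < 3:
            raise ValueError("need n >= 3 for a correlation")


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci95_low: float
    ci95_high: float
    n_pos: int
    n_neg: int
    se_method: str = "hanley-mcneil"

    def __post_init__(self):
        if not (self.ci95_low <= self.auc <= self.ci95_high):
            raise ValueError("CI must bracket the AUC")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes must be present")


def pearson(x: Sequence[float], y: Sequence[float],
            log_x: bool = False, log_y: bool = False) -> CorrelationResult:
    """Pearson r with two-sided p from the t distribution (n-2 df).

    Pairs with a missing value in either vector are dropped first.  Log
    transforms require strictly positive values and raise naming the first
    offending index.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    idx = np.flatnonzero(keep)
    for vec, flag, name in ((x, log_x, "x"), (y, log_y, "y")):
        if flag and (vec <= 0).any():
            bad = int(idx[np.argmax(vec <= 0)])
            raise ValueError(
                f"log transform of {name}: non-positive value at index {bad}")
    if log_x:
        x = np.log(x)
    if log_y:
        y = np.log(y)
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=n, p_value=float(p),
                             log_x=log_x, log_y=log_y)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """AUC of ``scores`` against binary ``labels`` (1 = condition present).

    Orientation is fixed: a higher score is taken to predict a positive
    label; no automatic flipping is applied, so an anti-discriminating
    score yields AUC < 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    keep = ~(np.isnan(scores) | np.isnan(labels))
    scores, labels = scores[keep], labels[keep]
    if not np.all(np.isin(labels, (0.0, 1.0))):
        raise ValueError("labels must be binary 0/1")
    labels = labels.astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    if np.all(scores == scores[0]):
        logger.warning("all scores tied; AUC degenerates to 0.5")
        return RocResult(auc=0.5, ci95_low=0.5, ci95_high=0.5,
                         n_pos=n_pos, n_neg=n_neg)
    # Mann-Whitney U via midranks
    ranks = stats.rankdata(scores, method="average")
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    z = stats.norm.ppf(0.975)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return RocResult(auc=float(auc), ci95_low=float(min(lo, auc)),
                     ci95_high=float(max(hi, auc)),
                     n_pos=n_pos, n_neg=n_neg)


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc)
           + (n_pos - 1) * (q1 - auc * auc)
           + (n_neg - 1) * (q2 - auc * auc)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def correlation_table(score_table: ScoreTable | pd.DataFrame,
                      primary: str,
                      comparators: Sequence[str],
                      log_primary: bool = False,
                      log_comparators: Optional[dict[str, bool]] = None
                      ) -> pd.DataFrame:
    """Correlate one primary score column against several comparators.

    One row per comparator, pairwise complete-case; cells that cannot be
    computed (empty overlap, degenerate variance) are reported missing
    with a logged warning rather than aborting the table.
    """
    df = score_table.data if isinstance(score_table, ScoreTable) else score_table
    if primary not in df.columns:
        raise KeyError(f"primary column {primary!r} not in table")
    log_comparators = log_comparators or {}
    rows = []
    for comp in comparators:
        if comp not in df.columns:
            logger.warning("comparator column %r missing; cell skipped", comp)
            rows.append({"comparator": comp, "r": np.nan, "n": 0,
                         "p_value": np.nan})
            continue
        try:
            res = pearson(df[primary], df[comp], log_x=log_primary,
                          log_y=log_comparators.get(comp, False))
            rows.append({"comparator": comp, "r": res.r, "n": res.n,
                         "p_value": res.p_value})
        except ValueError as exc:
            logger.warning("correlation %s ~ %s failed: %s",
                           primary, comp, exc)
            rows.append({"comparator": comp, "r": np.nan, "n": 0,
                         "p_value": np.nan})
    return pd.DataFrame(rows)


def write_report(corr: pd.DataFrame, rocs: dict[str, RocResult],
                 out_dir: str | Path, primary: str = "sims_score") -> None:
    """Write the correlation table, ROC table and a plain-text summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corr.to_csv(out_dir / "correlations.csv", index=False)
    roc_df = pd.DataFrame(
        [{"score": k, "auc": v.auc, "ci95_low": v.ci95_low,
          "ci95_high": v.ci95_high, "n_pos": v.n_pos, "n_neg": v.n_neg}
         for k, v in rocs.items()])
    roc_df.to_csv(out_dir / "roc.csv", index=False)

    lines = [f"Correlations with {primary}", "-" * 40]
    for _, row in corr.iterrows():
        r_str = "   n/a" if pd.isna(row["r"]) else f"{row['r']:6.3f}"
        lines.append(f"{row['comparator']:<40s} r = {r_str}  "
                     f"(n = {int(row['n'])})")
    lines += ["", "ROC analysis (state variable: dichotomous MS)", "-" * 40]
    for k, v in rocs.items():
        lines.append(f"{k:<40s} AUC = {v.auc:.3f} "
                     f"(95% CI {v.ci95_low:.3f}-{v.ci95_high:.3f}; "
                     f"n+ = {v.n_pos}, n- = {v.n_neg})")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
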