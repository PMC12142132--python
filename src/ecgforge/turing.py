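"""Statistics for visual Turing tests on real vs synthetic ECG images.

Observers vote "real" or "synthetic" on a mix of real-world photographs and
synthetic renders, optionally rating confidence on a 1-5 Likert scale.  This
module computes the discrimination summary: accuracy (all responses pooled),
true recognition rate (real items), false recognition rate (synthetic
items), each with 95% CIs; Fleiss' kappa for inter-observer agreement; and
the AUC-ROC of the signed-ordinal confidence score (vote=real -> +confidence,
vote=synthetic -> -confidence) for discriminating truly-real items.
Chance-level accuracy and AUC ~ 0.5 indicate the synthetic images pass the
Turing test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

REAL, SYNTHETIC = "real", "synthetic"
_REQUIRED = ("item_id", "truth", "rater_id", "vote")


class RatingTableError(ValueError):
    """Malformed or degenerate rating table."""


def load_ratings(path_or_df) -> pd.DataFrame:
    """Load and validate a rating table (CSV path or DataFrame).

    Columns: item_id, truth {real, synthetic}, rater_id, vote {real,
    synthetic}, optional confidence 1..5.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    df = df.copy()
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise RatingTableError(f"missing columns: {missing}")
    if len(df) == 0:
        raise RatingTableError("rating table is empty")
    for col in ("truth", "vote"):
        df[col] = df[col].astype(str).str.strip().str.lower()
        bad = set(df[col]) - {REAL, SYNTHETIC}
        if bad:
            raise RatingTableError(f"invalid {col} values: {sorted(bad)}")
    if df.duplicated(subset=["item_id", "rater_id"]).any():
        raise RatingTableError("duplicate (item_id, rater_id) rows")
    truth_per_item = df.groupby("item_id")["truth"].nunique()
    if (truth_per_item > 1).any():
        raise RatingTableError("conflicting truth labels within an item")
    if "confidence" in df.columns and df["confidence"].notna().any():
        conf = df["confidence"].dropna()
        if not conf.isin([1, 2, 3, 4, 5]).all():
            raise RatingTableError("confidence must be integers 1..5")
    return df


@dataclass
class RateEstimate:
    """A proportion with its 95% CI and the response count it pools."""

    point: float
    ci_low: float
    ci_high: float
    n: int

    def as_dict(self) -> dict:
        return {"point": self.point, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "n": self.n}


def _rate(correct: int, n: int, method: str) -> RateEstimate:
    if n == 0:
        raise RatingTableError("no responses for this truth class")
    p = correct / n
    lo, hi = proportion_confint(correct, n, alpha=0.05, method=method)
    return RateEstimate(point=p, ci_low=float(lo), ci_high=float(hi), n=n)


def accuracy_metrics(
    table: pd.DataFrame, ci_method: str = "normal",
) -> dict[str, RateEstimate]:
    """Accuracy, true recognition rate and false recognition rate.

    Accuracy pools every response; TRR is the proportion of responses on
    truly-real items voted real; FRR the proportion on synthetic items voted
    synthetic.  CIs are Wald ("normal") by default, matching the symmetric
    intervals conventional for these tests; pass ``ci_method="wilson"`` for
    Wilson intervals.
    """
    table = load_ratings(table)
    correct = table["vote"] == table["truth"]
    out = {"accuracy": _rate(int(correct.sum()), len(table), ci_method)}
    for name, cls in (("true_recognition_rate", REAL),
                      ("false_recognition_rate", SYNTHETIC)):
        sub = table["truth"] == cls
        if not sub.any():
            out[name] = None
            warnings.warn(f"no items with truth={cls}; {name} undefined")
            continue
        out[name] = _rate(int(correct[sub].sum()), int(sub.sum()), ci_method)
    return out


def fleiss_kappa(table: pd.DataFrame) -> RateEstimate:
    """Fleiss' kappa over the two vote categories, with a 95% CI.

    Requires every item rated by the same number n >= 2 of raters; items
    with a deviating count are dropped with a warning.  The CI uses the
    large-sample variance of kappa under the null of chance agreement
    (Fleiss 1971), the standard companion to the statistic.
    """
    table = load_ratings(table)
    counts = table.pivot_table(
        index="item_id", columns="vote", aggfunc="size", fill_value=0
    ).reindex(columns=[REAL, SYNTHETIC], fill_value=0)
    per_item = counts.sum(axis=1)
    n = int(per_item.mode().iloc[0])
    if (per_item != n).any():
        warnings.warn(
            f"dropping {(per_item != n).sum()} item(s) not rated by {n} raters"
        )
        counts = counts[per_item == n]
    if n < 2:
        raise RatingTableError("Fleiss' kappa needs >= 2 raters per item")
    m = counts.to_numpy(dtype=float)
    n_items = m.shape[0]
    p_j = m.sum(axis=0) / (n_items * n)
    p_e = float(np.sum(p_j**2))
    if p_e >= 1.0:
        raise RatingTableError(
            "all votes in one category: expected agreement is 1, kappa undefined"
        )
    p_i = (np.sum(m**2, axis=1) - n) / (n * (n - 1))
    p_bar = float(np.mean(p_i))
    kappa = (p_bar - p_e) / (1.0 - p_e)
    # Fleiss (1971) large-sample variance
    sum_pq = float(np.sum(p_j * (1 - p_j)))
    var = (2.0 / (n_items * n * (n - 1))) * (
        sum_pq**2 - float(np.sum(p_j * (1 - p_j) * (1 - 2 * p_j)))
    ) / sum_pq**2
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.975)
    return RateEstimate(
        point=float(kappa),
        ci_low=float(kappa - z * se),
        ci_high=float(kappa + z * se),
        n=n_items,
    )


def signed_scores(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(signed score, truth-is-real indicator) per response.

    The Likert confidence is given the sign of the vote: +c for "real",
    -c for "synthetic", yielding a 10-level ordinal discrimination score.
    """
    table = load_ratings(table)
    if "confidence" not in table.columns or table["confidence"].isna().any():
        raise RatingTableError("confidence required for every response")
    sign = np.where(table["vote"] == REAL, 1.0, -1.0)
    score = sign * table["confidence"].to_numpy(dtype=float)
    y = (table["truth"] == REAL).to_numpy()
    return score, y


def confidence_auc(table: pd.DataFrame) -> RateEstimate:
    """AUC-ROC of the signed confidence score for truly-real items.

    Mann-Whitney rank formulation with ties averaged; 95% CI from the
    Hanley-McNeil distribution-free variance.  An AUC below 0.5 is reported
    as-is (confidence anti-predicts the truth), never flipped.
    """
    score, y = signed_scores(table)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise RatingTableError("both truth classes required for AUC")
    ranks = stats.rankdata(score)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2)
           + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.975)
    return RateEstimate(
        point=float(auc),
        ci_low=float(max(0.0, auc - z * se)),
        ci_high=float(min(1.0, auc + z * se)),
        n=n_pos + n_neg,
    )


def turing_summary(table: pd.DataFrame, ci_method: str = "normal") -> dict:
    """Headline summary: rates, Fleiss' kappa and (if confidence present) AUC."""
    table = load_ratings(table)
    rates = accuracy_metrics(table, ci_method)
    out = {k: (v.as_dict() if v is not None else None) for k, v in rates.items()}
    try:
        out["fleiss_kappa"] = fleiss_kappa(table).as_dict()
    except RatingTableError as exc:
        out["fleiss_kappa"] = {"error": str(exc)}
    if "confidence" in table.columns and table["confidence"].notna().all():
        out["auc"] = confidence_auc(table).as_dict()
    return out
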