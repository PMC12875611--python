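"""Group statistics for symmetry scores and wound-assay outcome tables.

Symmetry scores are compared group-wise against the intact-limb group with
two-tailed Welch's t-tests (the intact limb being the reference "typical
asymmetric structure"); paired measurements use a paired t-test.  Outcome
count tables (regress / bump / limb per surgical condition) are summarised
as percentages, with Fisher's exact test available for 2×2 contrasts.

No multiple-testing correction is applied by default — per-class test
families are reported raw — but Benjamini–Hochberg adjustment is available
via ``bh=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "welch_t",
    "paired_t",
    "compare_to_intact",
    "outcome_rates",
    "fisher_2x2",
    "scores_to_table",
    "load_packaged_outcomes",
]

SCORE_COLUMNS = ("class_1", "class_2", "class_3", "class_4", "class_5", "combined")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_two_sided: float
    n: tuple[int, ...]
    test_name: str
    degenerate: bool = False


def welch_t(a, b) -> TestResult:
    """Two-tailed Welch's t-test (unequal variances, Welch–Satterthwaite df).

    Degenerate inputs are resolved explicitly: two zero-variance samples
    with equal means give t = 0, p = 1; zero variance on both sides with
    unequal means gives p = 0 with the ``degenerate`` flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError(f"each sample needs n >= 2, got {na} and {nb}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return TestResult(0.0, float(na + nb - 2), 1.0, (na, nb), "welch_t")
        return TestResult(
            float(np.sign(diff) * np.inf), float(na + nb - 2), 0.0, (na, nb),
            "welch_t", degenerate=True,
        )
    se2 = va / na + vb / nb
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), (na, nb), "welch_t")


def paired_t(a, b) -> TestResult:
    """Two-tailed paired t-test: one-sample t on the pairwise differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError(f"paired samples must have equal length ({a.size} != {b.size})")
    n = a.size
    if n < 2:
        raise ValueError("paired test needs n >= 2 pairs")
    d = a - b
    vd = d.var(ddof=1)
    if vd == 0.0:
        if d.mean() == 0.0:
            return TestResult(0.0, float(n - 1), 1.0, (n,), "paired_t")
        return TestResult(
            float(np.sign(d.mean()) * np.inf), float(n - 1), 0.0, (n,),
            "paired_t", degenerate=True,
        )
    t = d.mean() / np.sqrt(vd / n)
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult(float(t), float(n - 1), float(p), (n,), "paired_t")


def scores_to_table(records) -> pd.DataFrame:
    """Build a tidy score table from (group, SymmetryResult) pairs."""
    rows = []
    for group, res in records:
        row = {
            "group": group,
            "sample_id": res.provenance.get("sample_id", ""),
            "window_id": res.provenance.get("window_id", 0),
        }
        for c in range(1, 6):
            row[f"class_{c}"] = np.nan if res.scores[c] is None else res.scores[c]
        row["combined"] = res.combined
        rows.append(row)
    return pd.DataFrame(rows)


def compare_to_intact(
    scores: pd.DataFrame,
    intact_group: str,
    metrics: tuple[str, ...] | None = None,
    bh: bool = False,
) -> pd.DataFrame:
    """Welch-test every group and score column against the intact group.

    Returns a tidy frame (group, metric, statistic, df, p, n_group,
    n_intact); ``bh=True`` appends Benjamini–Hochberg adjusted p-values.
    """
    groups = scores["group"].unique().tolist()
    if intact_group not in groups:
        raise ValueError(f"intact group {intact_group!r} not present in the table")
    if metrics is None:
        metrics = tuple(c for c in SCORE_COLUMNS if c in scores.columns)
    rows = []
    intact = scores[scores["group"] == intact_group]
    for g in groups:
        if g == intact_group:
            continue
        other = scores[scores["group"] == g]
        for m in metrics:
            a = other[m].dropna().to_numpy()
            b = intact[m].dropna().to_numpy()
            res = welch_t(a, b)
            rows.append(
                {
                    "group": g,
                    "metric": m,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": res.p_two_sided,
                    "n_group": len(a),
                    "n_intact": len(b),
                    "degenerate": res.degenerate,
                }
            )
    out = pd.DataFrame(rows)
    if bh and len(out):
        out["p_bh"] = sps.false_discovery_control(out["p"].to_numpy(), method="bh")
    return out


def outcome_rates(tbl: pd.DataFrame) -> pd.DataFrame:
    """Per-condition outcome percentages, exact internally.

    Input columns: condition, N, regress, bump, limb with
    regress + bump + limb = N.  Output adds ``<outcome>_pct`` (float,
    exact value) and ``<outcome>_pct_display`` (one-decimal string,
    matching the conventional printed style).
    """
    required = {"condition", "N", "regress", "bump", "limb"}
    missing = required - set(tbl.columns)
    if missing:
        raise ValueError(f"outcome table is missing columns {sorted(missing)}")
    out = tbl.copy()
    for _, row in out.iterrows():
        counts = [int(row[k]) for k in ("regress", "bump", "limb")]
        if any(c < 0 for c in counts):
            raise ValueError(f"negative count in condition {row['condition']!r}")
        if int(row["N"]) == 0:
            raise ValueError(f"condition {row['condition']!r} has N = 0")
        if sum(counts) != int(row["N"]):
            raise ValueError(
                f"counts {counts} do not sum to N = {row['N']} for "
                f"condition {row['condition']!r}"
            )
    for k in ("regress", "bump", "limb"):
        exact = [
            Fraction(100 * int(c), int(n))
            for c, n in zip(out[k], out["N"])
        ]
        out[f"{k}_pct"] = [float(f) for f in exact]
        out[f"{k}_pct_display"] = [f"{float(f):.1f}" for f in exact]
    return out


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2×2 count table.

    The p-value sums hypergeometric probabilities of all tables (with the
    observed margins) no more likely than the observed one.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2×2 non-negative counts")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def load_packaged_outcomes() -> pd.DataFrame:
    """The packaged accessory-limb-model outcome count table."""
    with resources.as_file(
        resources.files("limbsym").joinpath("data/alm_outcomes.csv")
    ) as p:
        return pd.read_csv(Path(p))
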