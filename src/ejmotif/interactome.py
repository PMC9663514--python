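"""Interactor calling and class-specific tests for AP-MS / BioID LFQ tables.

The input is a long-format table of label-free quantification (LFQ)
intensities indexed by protein x (experiment, sample, fraction), where a
zero records "not detected" (the tables are strongly zero-inflated) and
every experiment contains a ``vector_control`` condition.  The pipeline:

1. fraction-sum normalization, summing fractions within a sample and
   equalizing per-experiment medians (``normalize_intensities``);
2. an empirical null per experiment fitted to the control totals with an
   Epanechnikov kernel (``epanechnikov_null``), from whose exact CDF
   upper-tail p-values are read;
3. Benjamini-Hochberg adjustment and a pseudolog2 fold-change threshold to
   flag significant interactors (``call_interactors``);
4. downstream set logic: a zero-inflated binary binomial test for
   class-specific preys (``binary_class_enrichment``), strict
   presence/absence filtering across cell lines, and overlap-significance
   arithmetic for annotation sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import EpanechnikovKDE, bh_adjust, fisher_combine

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "protein_id",
    "experiment",
    "sample",
    "fraction",
    "condition",
    "intensity",
]


@dataclass(frozen=True)
class InteractorCall:
    protein_id: str
    mean_pseudolog2_fc: float
    p_raw: float
    p_adj: float
    significant: bool


def pseudolog2(x, pseudocount: float = 1.0):
    """log2 with a pseudocount: pseudolog2(x) = log2(x + c)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("intensities must be nonnegative")
    return np.log2(x + pseudocount)


def normalize_intensities(table: pd.DataFrame) -> pd.DataFrame:
    """Fraction-sum normalization with per-experiment median equalization.

    Step 1: within every (experiment, sample, fraction) column, divide by
    the column total (fractions with zero total are dropped with a warning).
    Step 2: sum the normalized fractions within a sample per protein,
    yielding a total protein intensity per sample.  Step 3: rescale every
    experiment so the median *detected* (nonzero) protein total equals 1 —
    all per-experiment medians are equal on this scale, and one median unit
    is the natural pseudocount for pseudolog2 fold changes.

    Returns a long table with columns protein_id, experiment, sample,
    condition, total.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = table.copy()
    if np.any(df["intensity"] < 0):
        raise ValueError("intensities must be nonnegative")
    if not np.any(df["intensity"] > 0):
        raise ValueError("all-zero intensity table")

    frac_keys = ["experiment", "sample", "fraction"]
    totals = df.groupby(frac_keys)["intensity"].transform("sum")
    dead = totals == 0
    if dead.any():
        n_dropped = df.loc[dead, frac_keys].drop_duplicates().shape[0]
        warnings.warn(f"dropping {n_dropped} fraction(s) with zero total")
        logger.warning("dropping %d zero-total fraction(s)", n_dropped)
        df, totals = df[~dead], totals[~dead]
    df = df.assign(norm=df["intensity"] / totals)

    per_sample = (
        df.groupby(["protein_id", "experiment", "sample", "condition"],
                   as_index=False, observed=True)["norm"]
        .sum()
        .rename(columns={"norm": "total"})
    )

    def _rescale(g):
        detected = g.loc[g["total"] > 0, "total"]
        med = detected.median()
        g = g.copy()
        g["total"] = g["total"] / med
        return g

    out = (
        per_sample.groupby("experiment", group_keys=False)[per_sample.columns]
        .apply(_rescale)
        .reset_index(drop=True)
    )
    return out


def epanechnikov_null(control_values, bandwidth="auto") -> EpanechnikovKDE:
    """Empirical null over control totals (Epanechnikov KDE, exact CDF)."""
    return EpanechnikovKDE(control_values, bandwidth=bandwidth)


def call_interactors(
    totals: pd.DataFrame,
    bait_condition: str,
    control_condition: str = "vector_control",
    fc_threshold: float = 0.5,
    alpha: float = 0.05,
    bandwidth="auto",
    combine: str = "fisher",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Call significant bait interactors against the empirical control null.

    Parameters
    ----------
    totals : output of :func:`normalize_intensities`.
    combine : "fisher" (default) computes one p per experiment against that
        experiment's control null and combines them with Fisher's method
        (calibrated when experiments are independent; anti-conservative if
        protein abundances correlate strongly across experiments).
        "pooled" pools experiments before the p-value: the protein-level
        mean bait total is scored against the null of per-protein mean
        control totals.  Note the pooled path's p-value floor is
        1/(n_proteins+1), which bounds how small adjusted p-values can get.

    Returns a DataFrame with one row per protein seen in the bait condition:
    mean_pseudolog2_fc, p_raw, p_adj, significant.  A protein is significant
    iff mean_pseudolog2_fc > fc_threshold and p_adj <= alpha.
    """
    if combine not in ("fisher", "pooled"):
        raise ValueError("combine must be 'fisher' or 'pooled'")
    bait = totals[totals["condition"] == bait_condition]
    ctrl = totals[totals["condition"] == control_condition]
    if bait.empty or ctrl.empty:
        raise ValueError("bait or control condition absent from the table")

    experiments = sorted(bait["experiment"].unique())
    proteins = sorted(bait["protein_id"].unique())
    # per-experiment mean bait / control totals per protein (absent -> 0)
    bait_mean = (
        bait.groupby(["protein_id", "experiment"], observed=True)["total"]
        .mean()
        .unstack(fill_value=0.0)
        .reindex(index=proteins, columns=experiments, fill_value=0.0)
    )
    ctrl_mean = (
        ctrl.groupby(["protein_id", "experiment"], observed=True)["total"]
        .mean()
        .unstack(fill_value=0.0)
        .reindex(index=proteins, columns=experiments, fill_value=0.0)
    )

    fc = pseudolog2(bait_mean.values, pseudocount) - pseudolog2(
        ctrl_mean.values, pseudocount
    )
    mean_fc = fc.mean(axis=1)

    # The statistic and its null must be the same kind of summary: a
    # protein-level mean bait total is scored against the per-protein mean
    # control totals.  Pooling before the p-value ("pooled", default) keeps
    # raw p-values uniform under the null; the per-experiment-then-Fisher
    # path is also offered but is anti-conservative when protein abundances
    # are correlated across experiments (as they are in practice).
    # The KDE is fitted on the pseudolog2 scale: intensity totals span
    # orders of magnitude, and a single global bandwidth on the raw scale
    # over-smooths the bulk of the distribution.  The transform is
    # monotone, so the upper-tail probability is unchanged in definition.
    if combine == "pooled":
        ctrl_protein_mean = pseudolog2(
            ctrl.groupby("protein_id", observed=True)["total"].mean().values,
            pseudocount,
        )
        null = epanechnikov_null(ctrl_protein_mean, bandwidth)
        floor = 1.0 / (ctrl_protein_mean.size + 1)
        bait_protein_mean = (
            bait.groupby("protein_id", observed=True)["total"]
            .mean()
            .reindex(proteins, fill_value=0.0)
        )
        p_raw = np.maximum(
            null.sf(pseudolog2(bait_protein_mean.values, pseudocount)), floor
        )
    else:
        per_exp = np.empty((len(proteins), len(experiments)))
        for j, exp in enumerate(experiments):
            ctrl_e = pseudolog2(
                ctrl[ctrl["experiment"] == exp]
                .groupby("protein_id", observed=True)["total"]
                .mean()
                .values,
                pseudocount,
            )
            null = epanechnikov_null(ctrl_e, bandwidth)
            floor = 1.0 / (ctrl_e.size + 1)
            per_exp[:, j] = np.maximum(
                null.sf(pseudolog2(bait_mean[exp].values, pseudocount)), floor
            )
        p_raw = np.array([fisher_combine(row) for row in per_exp])

    p_adj = bh_adjust(p_raw)
    out = pd.DataFrame(
        {
            "protein_id": proteins,
            "mean_pseudolog2_fc": mean_fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    out["significant"] = (out["mean_pseudolog2_fc"] > fc_threshold) & (
        out["p_adj"] <= alpha
    )
    return out


def binary_class_enrichment(
    presence: pd.DataFrame,
    class_labels: dict,
    fold_threshold: float = 5.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Zero-inflated binary test for class-specific interactors.

    Interactome abundances are reduced to detected/not-detected per bait;
    for each prey protein with k_A presences among the m_A class-A baits and
    k_B among the m_B class-B baits, the representation ratio is
    r_A = (k_A/m_A)/(k_B/m_B) (infinite when k_B = 0 < k_A) and the p-value
    is the binomial tail P(X >= k_A) with X ~ Bin(k_A + k_B, m_A/(m_A+m_B)).
    A prey is class-A specific iff r_A >= fold_threshold and p_A < alpha
    (symmetrically for class B).

    Parameters
    ----------
    presence : binary DataFrame, proteins x baits.
    class_labels : bait -> "A" or "B" (or the JM-a-like / JM-b-like names).
    """
    norm = {"JM-a-like": "A", "JM-b-like": "B", "A": "A", "B": "B"}
    labels = {b: norm[v] for b, v in class_labels.items()}
    baits_a = [b for b in presence.columns if labels.get(b) == "A"]
    baits_b = [b for b in presence.columns if labels.get(b) == "B"]
    if not baits_a or not baits_b:
        raise ValueError("both classes must be non-empty")
    vals = presence[baits_a + baits_b].astype(bool).astype(int)
    m_a, m_b = len(baits_a), len(baits_b)
    rows = []
    for prot, row in vals.iterrows():
        k_a = int(row[baits_a].sum())
        k_b = int(row[baits_b].sum())
        if k_a + k_b == 0:
            continue  # absent everywhere: excluded, not an error
        frac_a, frac_b = k_a / m_a, k_b / m_b
        r_a = np.inf if (k_b == 0 and k_a > 0) else (
            frac_a / frac_b if frac_b > 0 else np.nan
        )
        r_b = np.inf if (k_a == 0 and k_b > 0) else (
            frac_b / frac_a if frac_a > 0 else np.nan
        )
        n = k_a + k_b
        p_a = float(stats.binom.sf(k_a - 1, n, m_a / (m_a + m_b)))
        p_b = float(stats.binom.sf(k_b - 1, n, m_b / (m_a + m_b)))
        spec = None
        if np.isfinite(r_a) or r_a == np.inf:
            if r_a >= fold_threshold and p_a < alpha:
                spec = "A"
        if spec is None and (np.isfinite(r_b) or r_b == np.inf):
            if r_b >= fold_threshold and p_b < alpha:
                spec = "B"
        rows.append(
            {
                "protein_id": prot,
                "k_A": k_a,
                "k_B": k_b,
                "ratio_A": r_a,
                "ratio_B": r_b,
                "p_A": p_a,
                "p_B": p_b,
                "specific": spec,
            }
        )
    return pd.DataFrame(rows)


def strict_presence_filter(condition_presence: dict, control_presence: dict,
                           group_keys=None) -> set:
    """Proteins present in the condition and absent in the matched control,
    intersected across groups (e.g. cell lines).

    Parameters
    ----------
    condition_presence, control_presence : group key -> set of protein ids.
    group_keys : which groups to intersect; default = all condition keys.
    """
    if group_keys is None:
        group_keys = list(condition_presence)
    if not group_keys:
        raise ValueError("empty group list")
    per_group = [
        set(condition_presence[g]) - set(control_presence.get(g, ()))
        for g in group_keys
    ]
    return set.intersection(*per_group)


def annotation_overlap_significance(
    observed_overlap: float, resampled_overlaps, tail: str = "lower"
) -> float:
    """Normal-fit p-value of an observed annotation overlap.

    A normal distribution is fitted to overlap values from random same-size
    draws; the p-value is the lower tail (hypothesis: *lack* of overlap) or
    upper tail at the observed value.
    """
    res = np.asarray(resampled_overlaps, dtype=float)
    if res.size < 2 or res.std(ddof=1) == 0:
        raise ValueError("need >= 2 resampled overlaps with nonzero variance")
    mu, sd = res.mean(), res.std(ddof=1)
    if tail == "lower":
        return float(stats.norm.cdf(observed_overlap, mu, sd))
    if tail == "upper":
        return float(stats.norm.sf(observed_overlap, mu, sd))
    raise ValueError("tail must be 'lower' or 'upper'")


def chi_square_overlap(table) -> tuple:
    """Chi-square test (1 df, no continuity correction) on a 2x2 table."""
    table = np.asarray(table)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a nonnegative 2x2 contingency table")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    assert dof == 1
    return float(stat), float(p)
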