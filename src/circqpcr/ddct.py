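"""Classic relative quantification: triplicate averaging, ΔCt against a
reference gene, 2^ΔΔCt fold changes, Tukey box-plot summaries and t tests.

Conventions
-----------
* ΔCt = Ct(target) − Ct(reference), within the same animal; computed within
  the same qPCR run when the reference was measured there, pooled across
  runs otherwise (within-run subtraction removes run offsets exactly).
* Fold change of an animal = 2^(mean ΔCt of the control group − ΔCt of the
  animal), so the control group centres at 1 by construction.
* Quartiles use linear interpolation (type 7); Tukey whiskers extend to the
  most extreme observation within 1.5×IQR of the quartiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in _STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


def average_technical_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (animal, primer, run) over detected replicates.

    Wells where every replicate is a non-detect keep ``ct = NaN`` with the
    non-detect flag propagated; mixed wells average the detected replicates
    and raise a partial-detect warning.
    """
    if len(records) == 0:
        raise ValidationError("empty Ct table")
    grouped = records.groupby(
        ["animal", "litter", "sex", "genotype", "run", "primer"], sort=True
    )["ct"]
    out = grouped.agg(
        ct="mean", n_detected="count", n_replicates="size"
    ).reset_index()
    partial = out[(out["n_detected"] > 0) & (out["n_detected"] < out["n_replicates"])]
    if len(partial):
        keys = [
            f"({r.animal}, {r.primer}, {r.run})" for r in partial.head(5).itertuples()
        ]
        warnings.warn(
            f"{len(partial)} well group(s) with partial non-detects, e.g. {', '.join(keys)}",
            UserWarning,
            stacklevel=2,
        )
    return out


def delta_ct(
    mean_ct: pd.DataFrame,
    reference_primer: str,
    within_run: bool = True,
) -> pd.DataFrame:
    """ΔCt per (animal, primer): target Ct minus reference Ct.

    With ``within_run=True`` the reference measured in the same run is used
    when available, falling back to the animal's pooled reference mean.
    Animals with no detected reference measurement are excluded with a
    warning.
    """
    if reference_primer not in set(mean_ct["primer"]):
        raise ValidationError(f"reference primer {reference_primer!r} not in table")
    ref = mean_ct[mean_ct["primer"] == reference_primer].dropna(subset=["ct"])
    ref_by_run = ref.set_index(["animal", "run"])["ct"]
    ref_by_animal = ref.groupby("animal")["ct"].mean()

    targets = mean_ct[mean_ct["primer"] != reference_primer].dropna(subset=["ct"])
    rows = []
    dropped = set()
    for r in targets.itertuples():
        if r.animal not in ref_by_animal.index:
            dropped.add(r.animal)
            continue
        if within_run and (r.animal, r.run) in ref_by_run.index:
            ref_ct = ref_by_run.loc[(r.animal, r.run)]
        else:
            ref_ct = ref_by_animal.loc[r.animal]
        rows.append(
            {
                "animal": r.animal,
                "litter": r.litter,
                "sex": r.sex,
                "genotype": r.genotype,
                "run": r.run,
                "primer": r.primer,
                "delta_ct": r.ct - ref_ct,
            }
        )
    if dropped:
        warnings.warn(
            f"animals dropped (no detected reference Ct): {sorted(dropped)}",
            UserWarning,
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def fold_change_2ddct(delta_cts: pd.DataFrame, control_genotype: str = "wt") -> pd.DataFrame:
    """2^ΔΔCt fold change per animal and primer, relative to the control
    group mean: FC = 2^(mean ΔCt(control) − ΔCt(animal)).

    Multiple-run ΔCt values are first averaged within animal.
    """
    if control_genotype not in set(delta_cts["genotype"]):
        raise ValidationError(f"empty control group {control_genotype!r}")
    per_animal = (
        delta_cts.groupby(["primer", "animal", "litter", "sex", "genotype"], sort=True)[
            "delta_ct"
        ]
        .mean()
        .reset_index()
    )
    out = []
    for primer, sub in per_animal.groupby("primer", sort=True):
        ctrl = sub.loc[sub["genotype"] == control_genotype, "delta_ct"]
        if len(ctrl) == 0:
            raise ValidationError(
                f"empty control group {control_genotype!r} for primer {primer!r}"
            )
        ctrl_mean = ctrl.mean()
        sub = sub.copy()
        sub["fold_change"] = 2.0 ** (ctrl_mean - sub["delta_ct"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def group_summary(fold_changes: pd.DataFrame, value: str = "fold_change") -> pd.DataFrame:
    """Tukey five-number summary per (primer, genotype).

    Whiskers reach the most extreme observations within 1.5×IQR of the
    quartile hinges; points beyond are listed as outliers.
    """
    if len(fold_changes) == 0:
        raise ValidationError("empty fold-change table")
    rows = []
    for (primer, genotype), sub in fold_changes.groupby(["primer", "genotype"], sort=True):
        x = np.sort(sub[value].to_numpy(dtype=float))
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # type-7 interpolation
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = x[(x >= lo_fence) & (x <= hi_fence)]
        outliers = x[(x < lo_fence) | (x > hi_fence)]
        rows.append(
            {
                "primer": primer,
                "genotype": genotype,
                "n": len(x),
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": inside.min() if len(inside) else np.nan,
                "whisker_high": inside.max() if len(inside) else np.nan,
                "outliers": ";".join(f"{v:g}" for v in outliers),
            }
        )
    return pd.DataFrame(rows)


def t_test(
    group_a,
    group_b,
    mode: str = "welch",
) -> tuple[float, float, str]:
    """Two-sided two-group test with significance stars.

    Modes: ``student`` (pooled variance), ``welch`` (default; robust to
    unequal variances), ``paired`` (groups are matched pairs in order) and
    ``mannwhitney`` (rank-based). Stars: * p<0.05, ** p<0.01, *** p<0.001.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(f"need >= 2 observations per group, got {len(a)} and {len(b)}")
    if mode == "student":
        stat, p = stats.ttest_ind(a, b, equal_var=True)
    elif mode == "welch":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    elif mode == "paired":
        if len(a) != len(b):
            raise ValidationError("paired mode requires equal group sizes")
        diffs = a - b
        if np.std(diffs, ddof=1) == 0.0 and np.mean(diffs) != 0.0:
            warnings.warn(
                "constant non-zero paired differences: t statistic is unbounded, p -> 0",
                UserWarning,
                stacklevel=2,
            )
            return float(np.sign(np.mean(diffs)) * np.inf), 0.0, "***"
        stat, p = stats.ttest_rel(a, b)
    elif mode == "mannwhitney":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValidationError(f"unknown test mode {mode!r}")
    return float(stat), float(p), significance_stars(float(p))


def ddct_pipeline(
    records: pd.DataFrame,
    reference_primer: str,
    control_genotype: str = "wt",
    within_run: bool = True,
    test_mode: str = "welch",
) -> dict[str, pd.DataFrame]:
    """Full baseline analysis: averaging → ΔCt → fold changes → summaries
    → per-primer tests of each non-control genotype against control."""
    means = average_technical_replicates(records)
    dct = delta_ct(means, reference_primer, within_run=within_run)
    fc = fold_change_2ddct(dct, control_genotype)
    summary = group_summary(fc)
    tests = []
    for primer, sub in fc.groupby("primer", sort=True):
        ctrl = sub.loc[sub["genotype"] == control_genotype, "fold_change"].to_numpy()
        for genotype in sorted(set(sub["genotype"]) - {control_genotype}):
            grp = sub.loc[sub["genotype"] == genotype, "fold_change"].to_numpy()
            if len(ctrl) < 2 or len(grp) < 2:
                continue
            stat, p, stars = t_test(ctrl, grp, mode=test_mode)
            tests.append(
                {
                    "primer": primer,
                    "genotype": genotype,
                    "control": control_genotype,
                    "mode": test_mode,
                    "statistic": stat,
                    "p_value": p,
                    "stars": stars,
                }
            )
    return {
        "mean_ct": means,
        "delta_ct": dct,
        "fold_change": fc,
        "summary": summary,
        "tests": pd.DataFrame(tests),
    }
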