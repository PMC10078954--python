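"""Library normalization, filtering, fold changes, permutation FDR and
circ-vs-host classification for back-spliced-junction count tables.

The normalization scales each sample's counts to a common (median) library
size; circRNAs whose mean normalized BSJ count across all samples falls
below a threshold (default 3) are excluded from statistics. Significance
is assessed by a label-permutation test on |log2FC| with Benjamini-
Hochberg correction — a distribution-free stand-in appropriate at these
group sizes — and significant circRNAs are classified against their host
gene's linear fold change.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import comb
from statsmodels.stats.multitest import multipletests

from .types import BsjCountTable, GeneCountTable, ValidationError

CATEGORIES = (
    "concordant",
    "circ_amplified",
    "inverse",
    "circ_only",
    "filtered",
    "not_significant",
)


def normalize_counts(
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each sample to the median library: counts × (median lib / own lib).

    ``library_sizes`` defaults to the table's own column sums; pass the
    host-gene column sums to normalize a BSJ table by total library depth.
    Returns the normalized table and the library sizes used.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.astype(float).reindex(counts.columns)
    zero = library_sizes[library_sizes <= 0]
    if len(zero):
        raise ValidationError(f"all-zero/invalid library for sample {zero.index[0]!r}")
    median_lib = float(library_sizes.median())
    norm = counts * (median_lib / library_sizes)
    return norm, library_sizes.rename("library_size")


def filter_min_bsj(
    normalized: pd.DataFrame, threshold: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition circRNAs by mean normalized BSJ count across all samples.

    Kept iff the mean is ≥ threshold (boundary inclusive); the partition is
    exact: every row lands in exactly one of (kept, removed).
    """
    means = normalized.mean(axis=1)
    keep = means >= threshold
    return normalized.loc[keep], normalized.loc[~keep]


def log2fc(
    normalized: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-feature log2[(mean_b + pc) / (mean_a + pc)], group a as baseline."""
    a_cols = groups.index[groups == group_a]
    b_cols = groups.index[groups == group_b]
    if len(a_cols) == 0 or len(b_cols) == 0:
        raise ValidationError(f"empty group among {group_a!r}/{group_b!r}")
    mean_a = normalized[a_cols].mean(axis=1)
    mean_b = normalized[b_cols].mean(axis=1)
    return np.log2((mean_b + pseudocount) / (mean_a + pseudocount)).rename("log2fc")


def permutation_fdr(
    normalized: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    n_permutations: int = 10_000,
    pseudocount: float = 0.5,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> pd.DataFrame:
    """Two-sided permutation test on |log2FC| with BH-adjusted FDR.

    p = (1 + #{permuted splits with |log2FC| ≥ observed}) / (1 + n_perm),
    the add-one convention that keeps p > 0. All distinct relabelings are
    enumerated when their number is ≤ 10,000 (or when ``exhaustive=True``);
    there the observed split itself plays the add-one role, so
    p = #{splits with |log2FC| ≥ observed} / n_splits — the exact quantity
    the Monte-Carlo estimator converges to. Designs allowing fewer than 20
    distinct splits are rejected.
    """
    cols = [c for c in normalized.columns if groups.get(c) in (group_a, group_b)]
    labels = groups.loc[cols]
    n_b = int((labels == group_b).sum())
    n_total = len(cols)
    if n_b == 0 or n_b == n_total:
        raise ValidationError(f"empty group among {group_a!r}/{group_b!r}")
    n_splits = int(comb(n_total, n_b, exact=True))
    if n_splits < 20:
        raise ValidationError(
            f"only {n_splits} distinct label permutations possible; need >= 20"
        )
    mat = normalized[cols].to_numpy(dtype=float)

    def lfc_for(b_mask: np.ndarray) -> np.ndarray:
        mean_b = mat[:, b_mask].mean(axis=1)
        mean_a = mat[:, ~b_mask].mean(axis=1)
        return np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    obs_mask = (labels == group_b).to_numpy()
    obs = np.abs(lfc_for(obs_mask))

    if exhaustive is None:
        exhaustive = n_splits <= 10_000
    exceed = np.zeros(len(normalized), dtype=int)
    if exhaustive:
        # all splits including the observed one, which always exceeds:
        # p = count / n_splits, the limit of the add-one MC estimator
        for idx in combinations(range(n_total), n_b):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(idx)] = True
            exceed += np.abs(lfc_for(mask)) >= obs - 1e-12
        p = exceed / n_splits
    else:
        rng = np.random.default_rng(seed)
        n_perm = n_permutations
        base = np.zeros(n_total, dtype=bool)
        base[:n_b] = True
        for _ in range(n_perm):
            mask = rng.permutation(base)
            exceed += np.abs(lfc_for(mask)) >= obs - 1e-12
        p = (1.0 + exceed) / (1.0 + n_perm)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"log2fc": lfc_for(obs_mask), "p_value": p, "fdr": fdr},
        index=normalized.index,
    )


def classify_circ_vs_host(
    circ_results: pd.DataFrame,
    linear_results: pd.DataFrame,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Classify circRNAs against their host gene's linear fold change.

    ``circ_results`` needs columns ``host_gene, log2fc, fdr`` (and
    optionally a boolean ``filtered``); ``linear_results`` is indexed by
    gene with columns ``log2fc, fdr``. For circRNAs passing the
    significance criterion (|log2FC| > lfc_threshold and FDR <
    fdr_threshold):

    * ``circ_only``      — host gene not significant (FDR at the same
      threshold; the fold-change magnitude criterion is not applied to the
      host, so a reliably detected sub-twofold host shift still counts as a
      host response);
    * ``inverse``        — host significant, opposite sign (|host LFC| > 0);
    * ``circ_amplified`` — same sign, circRNA shifted by the larger factor;
    * ``concordant``     — otherwise.

    Rows with ``filtered=True`` keep category ``filtered``; non-significant
    kept rows get ``not_significant``. Every row receives exactly one
    category. The summary also counts circRNAs past a plain twofold
    criterion (|log2FC| > 1) on normalized means.
    """
    missing = sorted(set(circ_results["host_gene"]) - set(linear_results.index))
    if missing:
        raise ValidationError(f"host genes missing from linear results: {missing}")
    out = circ_results.copy()
    cats = []
    for row in out.itertuples():
        if getattr(row, "filtered", False):
            cats.append("filtered")
            continue
        sig_c = abs(row.log2fc) > lfc_threshold and row.fdr < fdr_threshold
        if not sig_c:
            cats.append("not_significant")
            continue
        host = linear_results.loc[row.host_gene]
        out.loc[row.Index, "log2fc_linear"] = host["log2fc"]
        out.loc[row.Index, "fdr_linear"] = host["fdr"]
        sig_h = host["fdr"] < fdr_threshold
        if not sig_h:
            cats.append("circ_only")
        elif row.log2fc * host["log2fc"] < 0 and abs(host["log2fc"]) > 0:
            cats.append("inverse")
        elif abs(row.log2fc) > abs(host["log2fc"]):
            cats.append("circ_amplified")
        else:
            cats.append("concordant")
    out["category"] = cats
    hosts = linear_results.reindex(out["host_gene"])
    out["log2fc_linear"] = hosts["log2fc"].to_numpy()
    out["fdr_linear"] = hosts["fdr"].to_numpy()
    return out


def twofold_counts(classified: pd.DataFrame) -> dict[str, int]:
    """Counts of kept circRNAs shifted more than twofold either way."""
    kept = classified[~classified.get("filtered", pd.Series(False, index=classified.index))]
    return {
        "n_up_twofold": int((kept["log2fc"] > 1.0).sum()),
        "n_down_twofold": int((kept["log2fc"] < -1.0).sum()),
    }


def circ_linear_pipeline(
    bsj: BsjCountTable,
    genes: GeneCountTable,
    group_a: str = "wt",
    group_b: str = "hom",
    min_bsj: float = 3.0,
    pseudocount: float = 0.5,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """normalize → filter → log2FC + permutation FDR → classify.

    BSJ counts are normalized by total gene-table library depth; genes by
    their own. The normalization here stands in for the depth scaling the
    upstream circRNA quantifiers perform; it is scale-free (invariant to
    uniform library scaling).

    Returns a dict with the classified result table, volcano/scatter plot
    coordinate tables (x = log2FC, y = −log10 FDR; x/y = group-mean
    normalized counts) and the twofold summary counts.
    """
    lib = genes.counts.sum(axis=0)
    circ_norm, lib_used = normalize_counts(bsj.counts, library_sizes=lib)
    gene_norm, _ = normalize_counts(genes.counts, library_sizes=lib)
    kept, removed = filter_min_bsj(circ_norm, threshold=min_bsj)

    groups = bsj.sample_groups
    circ_stats = permutation_fdr(
        kept, groups, group_a, group_b,
        n_permutations=n_permutations, pseudocount=pseudocount, seed=seed,
    )
    gene_stats = permutation_fdr(
        gene_norm, genes.sample_groups, group_a, group_b,
        n_permutations=n_permutations, pseudocount=pseudocount, seed=seed + 1,
    )

    a_cols = groups.index[groups == group_a]
    b_cols = groups.index[groups == group_b]
    circ_all = pd.concat([kept, removed])
    result = pd.DataFrame(
        {
            "host_gene": bsj.meta["host_gene"].reindex(circ_all.index),
            "mean_norm_bsj": circ_all.mean(axis=1),
            f"mean_norm_{group_a}": circ_all[a_cols].mean(axis=1),
            f"mean_norm_{group_b}": circ_all[b_cols].mean(axis=1),
            "filtered": [cid in removed.index for cid in circ_all.index],
        }
    )
    result["log2fc"] = circ_stats["log2fc"].reindex(result.index)
    result["p_value"] = circ_stats["p_value"].reindex(result.index)
    result["fdr"] = circ_stats["fdr"].reindex(result.index)
    classified = classify_circ_vs_host(
        result, gene_stats, lfc_threshold=lfc_threshold, fdr_threshold=fdr_threshold
    )
    classified.index.name = "circ_id"

    volcano = pd.DataFrame(
        {
            "log2fc": circ_stats["log2fc"],
            "neg_log10_fdr": -np.log10(circ_stats["fdr"]),
        }
    )
    scatter = pd.DataFrame(
        {
            f"mean_norm_{group_b}": kept[b_cols].mean(axis=1),
            f"mean_norm_{group_a}": kept[a_cols].mean(axis=1),
        }
    )
    return {
        "results": classified,
        "gene_stats": gene_stats,
        "volcano": volcano,
        "scatter": scatter,
        "library_sizes": lib_used,
        "summary": twofold_counts(classified),
    }
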