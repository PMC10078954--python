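"""Synthetic data with the nested structure of a mouse qPCR study.

The Ct simulator draws one varying intercept per qPCR run, litter and animal
and adds per-replicate Normal noise whose SD may differ between primers and
runs, reproducing the correlation structure a hierarchical model of such
data must account for. Ground truth is returned alongside, so parameter
recovery and interval calibration can be tested.

The count simulator emits CIRI-style back-spliced-junction (BSJ) count
tables paired with host-gene linear counts, negative-binomially dispersed
with per-sample library-size scaling.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .types import (
    BsjCountTable,
    CohortDesign,
    CountSimParams,
    CT_COLUMNS,
    GeneCountTable,
    GenotypeGroup,
    GroundTruth,
    PrimerInfo,
    PrimerMap,
    ValidationError,
    parse_circ_id,
)

#: Plate cycle ceiling: wells with no crossing by this cycle are non-detects.
NONDETECT_CEILING = 40.0
#: Targets with Ct above this are physiologically scarce; quantification is
#: noisy there, so the simulator attaches a low-confidence warning flag.
LOW_CONFIDENCE_CT = 30.0


def default_primer_map() -> PrimerMap:
    """Primer panel for a typical circRNA qPCR assay: a circRNA and an
    alternative exon with their canonical linear mates, plus Gapdh."""
    return PrimerMap(
        [
            PrimerInfo("Gapdh", "reference", "Gapdh"),
            PrimerInfo("Rims2_lin", "linear", "Rims2"),
            PrimerInfo("Rims2_circ", "circular", "Rims2", paired_canonical="Rims2_lin"),
            PrimerInfo("Ntm_lin", "linear", "Ntm"),
            PrimerInfo("Ntm_alt", "alt_exon", "Ntm", paired_canonical="Ntm_lin"),
        ]
    )


def default_cohort(primer_map: PrimerMap | None = None) -> CohortDesign:
    """A common mouse sequencing-cohort shape: 6 homozygous mutants (4M/2F)
    vs 4 wild types (2M/2F), 3 litters, 2 qPCR runs, technical triplicates."""
    return CohortDesign(
        genotypes=[
            GenotypeGroup("wt", 4, 2, 2),
            GenotypeGroup("hom", 6, 4, 2),
        ],
        n_litters=3,
        n_runs=2,
        primers=primer_map or default_primer_map(),
        replicates_per_well=3,
    )


def qpcr_cohort(primer_map: PrimerMap | None = None) -> CohortDesign:
    """Larger qPCR validation cohort (≈10 animals per genotype, 4 litters)."""
    return CohortDesign(
        genotypes=[
            GenotypeGroup("wt", 10, 5, 5),
            GenotypeGroup("hom", 10, 6, 4),
        ],
        n_litters=4,
        n_runs=3,
        primers=primer_map or default_primer_map(),
        replicates_per_well=3,
    )


def default_truth(
    primer_map: PrimerMap | None = None,
    mutant_genotype: str = "hom",
    circ_shift_cycles: float = 1.0,
) -> GroundTruth:
    """Ground truth with a circRNA-specific deficit in the mutant.

    A shift of +1 cycle for the circular/alt-exon primers at efficiency 2
    halves the circular proportion (true Q = 0.5) while the canonical linear
    transcripts stay put — the qualitative pattern of interest.
    """
    pm = primer_map or default_primer_map()
    baseline = {}
    gshift: dict[tuple[str, str], float] = {}
    sshift: dict[tuple[str, str], float] = {}
    for p in pm:
        if p.species_role == "reference":
            baseline[p.primer_id] = 18.0
        elif p.species_role == "linear":
            baseline[p.primer_id] = 22.0
        else:
            baseline[p.primer_id] = 24.0
            gshift[(p.primer_id, mutant_genotype)] = circ_shift_cycles
        sshift[(p.primer_id, "M")] = 0.1
    return GroundTruth(
        baseline_ct=baseline,
        genotype_shift=gshift,
        sex_shift=sshift,
        sd_run=0.5,
        sd_litter=0.3,
        sd_animal=0.5,
        eta0=math.log(0.25),
        eta_primer={p.primer_id: 0.0 for p in pm},
        eta_run={},
        efficiency={p.primer_id: p.efficiency for p in pm},
    )


def _check_consistent(design: CohortDesign, truth: GroundTruth) -> None:
    primer_ids = set(design.primers.primer_ids)
    genotypes = set(design.genotype_labels)
    for p in truth.baseline_ct:
        if p not in primer_ids:
            raise ValidationError(f"ground truth references unknown primer {p!r}")
    for p in primer_ids:
        if p not in truth.baseline_ct:
            raise ValidationError(f"no baseline Ct for primer {p!r}")
    for (p, g) in truth.genotype_shift:
        if p not in primer_ids:
            raise ValidationError(f"genotype_shift references unknown primer {p!r}")
        if g not in genotypes:
            raise ValidationError(f"genotype_shift references unknown genotype {g!r}")
    for (p, s) in truth.sex_shift:
        if p not in primer_ids:
            raise ValidationError(f"sex_shift references unknown primer {p!r}")
        if s not in ("M", "F"):
            raise ValidationError(f"sex_shift references unknown sex {s!r}")


def simulate_ct_dataset(
    design: CohortDesign,
    truth: GroundTruth,
    seed: int,
    nondetect_ceiling: float = NONDETECT_CEILING,
    low_confidence_ct: float = LOW_CONFIDENCE_CT,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long-format Ct table under ``truth``.

    Animals are assigned to litters and runs round-robin within genotype so
    every run and litter mixes genotypes (a confounded design would make
    genotype effects unidentifiable from run effects). Each animal's plate
    work happens in a single run. Ct values exceeding ``nondetect_ceiling``
    are flagged as non-detects (``ct = NaN``); detected values above
    ``low_confidence_ct`` get ``low_confidence = True``.

    Returns the table (one row per technical replicate) and the ground
    truth unchanged, for recovery tests.
    """
    _check_consistent(design, truth)
    rng = np.random.default_rng(seed)

    runs = [f"run{i + 1}" for i in range(design.n_runs)]
    litters = [f"L{i + 1}" for i in range(design.n_litters)]
    u = {r: rng.normal(0.0, truth.sd_run) for r in runs}
    v = {l: rng.normal(0.0, truth.sd_litter) for l in litters}

    animals: list[dict] = []
    counter = 0
    for group in design.genotypes:
        sexes = ["M"] * group.n_male + ["F"] * group.n_female
        for i, sex in enumerate(sexes):
            animals.append(
                {
                    "animal": f"{group.label}{i + 1:02d}",
                    "genotype": group.label,
                    "sex": sex,
                    "litter": litters[counter % len(litters)],
                    "run": runs[counter % len(runs)],
                }
            )
            counter += 1
    w = {a["animal"]: rng.normal(0.0, truth.sd_animal) for a in animals}

    rows = []
    for a in animals:
        for primer in design.primers.primer_ids:
            mu = (
                truth.baseline_ct[primer]
                + truth.genotype_shift.get((primer, a["genotype"]), 0.0)
                + truth.sex_shift.get((primer, a["sex"]), 0.0)
                + u[a["run"]]
                + v[a["litter"]]
                + w[a["animal"]]
            )
            sd = truth.residual_sd(primer, a["run"])
            for k in range(design.replicates_per_well):
                ct = mu + rng.normal(0.0, sd) if sd > 0 else mu
                nondetect = ct > nondetect_ceiling
                rows.append(
                    {
                        "animal": a["animal"],
                        "litter": a["litter"],
                        "sex": a["sex"],
                        "genotype": a["genotype"],
                        "run": a["run"],
                        "primer": primer,
                        "replicate": k + 1,
                        "ct": np.nan if nondetect else ct,
                        "low_confidence": (not nondetect) and ct > low_confidence_ct,
                    }
                )
    df = pd.DataFrame(rows, columns=CT_COLUMNS + ["low_confidence"])
    return df, truth


def default_count_params(
    n_wt: int = 4,
    n_hom: int = 6,
    n_circ: int = 30,
    seed_structure: int = 12345,
) -> CountSimParams:
    """Count-simulation parameters emulating a cerebellar circRNA screen.

    A minority of circRNAs are strongly depleted in the mutant (|log2FC|
    ≈ 1.5–2.5) while their host genes barely move — the discordant pattern
    under study — and the rest are null. Baselines span the dynamic range
    so the mean-normalized-BSJ filter has something to remove.
    """
    rng = np.random.default_rng(seed_structure)
    circ: dict[str, tuple[str, float, float]] = {}
    genes: dict[str, tuple[float, float]] = {}
    for i in range(n_circ):
        gene = f"Gene{i + 1:03d}"
        chrom = f"chr{1 + i % 19}"
        start = 1_000_000 + 10_000 * i
        cid = f"{chrom}:{start}|{start + 5_000}"
        base = float(rng.choice([0.5, 2.0, 8.0, 30.0, 120.0]))
        if i % 5 == 0:
            lfc = float(rng.choice([-2.5, -2.0, -1.5, 1.5, 2.0]))
        else:
            lfc = 0.0
        circ[cid] = (gene, base, lfc)
        genes[gene] = (float(rng.uniform(200, 5000)), float(rng.normal(0.0, 0.15)))
    return CountSimParams(
        n_samples_per_group={"wt": n_wt, "hom": n_hom},
        library_size_mean=2.0e7,
        library_size_cv=0.2,
        nb_dispersion=0.1,
        circ_baselines=circ,
        gene_baselines=genes,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        n = 1.0 / dispersion
        p = n / (n + mean[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


def simulate_count_tables(
    params: CountSimParams,
    seed: int,
    mutant_group: str = "hom",
    control_group: str = "wt",
) -> tuple[BsjCountTable, GeneCountTable, pd.DataFrame]:
    """Simulate paired BSJ and host-gene count tables.

    Baselines are in counts-per-(mean)-library units; each sample's expected
    count is scaled by its own library size. Returns the two tables and a
    truth frame with the true log2 fold changes (mutant vs control).
    """
    rng = np.random.default_rng(seed)
    sample_names: list[str] = []
    groups: list[str] = []
    for group, n in params.n_samples_per_group.items():
        for i in range(n):
            sample_names.append(f"{group}_{i + 1}")
            groups.append(group)
    sample_groups = pd.Series(groups, index=sample_names, name="genotype")

    sigma = math.sqrt(math.log(1.0 + params.library_size_cv**2)) if params.library_size_cv else 0.0
    lib = params.library_size_mean * np.exp(
        rng.normal(-0.5 * sigma**2, sigma, size=len(sample_names))
    )
    if (lib <= 0).any():
        raise ValidationError("non-positive library size drawn")
    lib_factor = lib / params.library_size_mean

    is_mut = np.array([g == mutant_group for g in groups])

    def expected(base: float, lfc: float) -> np.ndarray:
        fold = np.where(is_mut, 2.0**lfc, 1.0)
        return base * fold * lib_factor

    circ_rows, meta_rows, truth_rows = [], [], []
    for cid, (gene, base, lfc) in params.circ_baselines.items():
        circ_rows.append(_nb_draw(rng, expected(base, lfc), params.nb_dispersion))
        chrom, start, end = parse_circ_id(cid)
        meta_rows.append(
            {"circ_id": cid, "host_gene": gene, "chrom": chrom, "start": start,
             "end": end, "strand": "+"}
        )
        truth_rows.append({"feature": cid, "kind": "circ", "true_log2fc": lfc})
    gene_rows = []
    for gid, (base, lfc) in params.gene_baselines.items():
        gene_rows.append(_nb_draw(rng, expected(base, lfc), params.nb_dispersion))
        truth_rows.append({"feature": gid, "kind": "gene", "true_log2fc": lfc})

    circ_index = pd.Index(list(params.circ_baselines), name="circ_id")
    bsj = BsjCountTable(
        counts=pd.DataFrame(np.array(circ_rows), index=circ_index, columns=sample_names),
        meta=pd.DataFrame(meta_rows).set_index("circ_id"),
        sample_groups=sample_groups,
    )
    gene_index = pd.Index(list(params.gene_baselines), name="gene_id")
    genes = GeneCountTable(
        counts=pd.DataFrame(np.array(gene_rows), index=gene_index, columns=sample_names),
        sample_groups=sample_groups,
    )
    return bsj, genes, pd.DataFrame(truth_rows)
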