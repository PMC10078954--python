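"""Domain types shared across the package.

The central objects are the qPCR cohort description (:class:`CohortDesign`),
the generative ground truth used by the simulator (:class:`GroundTruth`),
the primer annotation table (:class:`PrimerMap`) and the result containers
for posterior ratio estimates and circRNA count tables.

Ct tables themselves are plain :class:`pandas.DataFrame` objects in long
format with columns ``animal, litter, sex, genotype, run, primer, replicate,
ct`` where a ``NaN`` Ct marks a non-detect (no threshold crossing within the
run's cycle ceiling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Column order of a long-format Ct table.
CT_COLUMNS = ["animal", "litter", "sex", "genotype", "run", "primer", "replicate", "ct"]

#: Recognized molecular roles of a primer pair.
SPECIES_ROLES = ("circular", "linear", "alt_exon", "reference")

SEXES = ("F", "M")


class ValidationError(ValueError):
    """Raised whenever an input table or parameter set violates a contract."""


@dataclass(frozen=True)
class PrimerInfo:
    """Annotation of one primer pair.

    Parameters
    ----------
    primer_id:
        Label used in Ct tables.
    species_role:
        One of ``circular`` (amplicon spans the back-spliced junction),
        ``linear`` (canonical linear mRNA), ``alt_exon`` (circRNA-enriched
        alternative exon) or ``reference`` (housekeeping gene, e.g. Gapdh).
    host_gene:
        Gene the amplicon derives from.
    paired_canonical:
        For ``circular``/``alt_exon`` primers, the ``linear`` primer on the
        same host gene that serves as the canonical product in ratio
        estimands.
    efficiency:
        Amplification efficiency as fold amplification per cycle, in
        ``(1, 2]``; 2.0 is perfect doubling.
    """

    primer_id: str
    species_role: str
    host_gene: str
    paired_canonical: str | None = None
    efficiency: float = 2.0


class PrimerMap:
    """Validated collection of :class:`PrimerInfo` records."""

    def __init__(self, primers: Sequence[PrimerInfo]):
        self._primers: dict[str, PrimerInfo] = {}
        for p in primers:
            if p.primer_id in self._primers:
                raise ValidationError(f"duplicate primer id {p.primer_id!r}")
            self._primers[p.primer_id] = p
        self.validate()

    def validate(self) -> None:
        roles = {p.species_role for p in self}
        for p in self:
            if not p.primer_id or not p.host_gene:
                raise ValidationError("primer_id and host_gene must be non-empty")
            if p.species_role not in SPECIES_ROLES:
                raise ValidationError(
                    f"primer {p.primer_id!r}: unknown species_role {p.species_role!r}"
                )
            if not (1.0 < p.efficiency <= 2.0):
                raise ValidationError(
                    f"primer {p.primer_id!r}: efficiency {p.efficiency} outside (1, 2]"
                )
            if p.species_role in ("circular", "alt_exon"):
                if p.paired_canonical is None:
                    raise ValidationError(
                        f"primer {p.primer_id!r} ({p.species_role}) lacks a paired canonical primer"
                    )
                mate = self._primers.get(p.paired_canonical)
                if mate is None:
                    raise ValidationError(
                        f"primer {p.primer_id!r}: paired canonical {p.paired_canonical!r} not in map"
                    )
                if mate.species_role != "linear":
                    raise ValidationError(
                        f"primer {p.primer_id!r}: paired primer {mate.primer_id!r} has role "
                        f"{mate.species_role!r}, expected 'linear'"
                    )
                if mate.host_gene != p.host_gene:
                    raise ValidationError(
                        f"primer {p.primer_id!r} and its canonical mate {mate.primer_id!r} "
                        "are on different host genes"
                    )
        if "reference" not in roles:
            raise ValidationError("primer map must contain at least one reference primer")

    def __iter__(self) -> Iterator[PrimerInfo]:
        return iter(self._primers.values())

    def __contains__(self, primer_id: str) -> bool:
        return primer_id in self._primers

    def __len__(self) -> int:
        return len(self._primers)

    def __getitem__(self, primer_id: str) -> PrimerInfo:
        try:
            return self._primers[primer_id]
        except KeyError:
            raise ValidationError(f"unknown primer {primer_id!r}") from None

    @property
    def primer_ids(self) -> list[str]:
        return list(self._primers)

    @property
    def reference_primers(self) -> list[str]:
        return [p.primer_id for p in self if p.species_role == "reference"]

    def efficiency(self, primer_id: str) -> float:
        return self[primer_id].efficiency

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "primer": p.primer_id,
                    "species_role": p.species_role,
                    "host_gene": p.host_gene,
                    "paired_canonical": p.paired_canonical or "",
                    "efficiency": p.efficiency,
                }
                for p in self
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PrimerMap":
        required = {"primer", "species_role", "host_gene"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"primer map missing columns: {sorted(missing)}")
        primers = []
        for _, row in df.iterrows():
            paired = row.get("paired_canonical", "")
            paired = None if (pd.isna(paired) or paired == "") else str(paired)
            eff = float(row.get("efficiency", 2.0)) if "efficiency" in df.columns else 2.0
            primers.append(
                PrimerInfo(
                    primer_id=str(row["primer"]),
                    species_role=str(row["species_role"]),
                    host_gene=str(row["host_gene"]),
                    paired_canonical=paired,
                    efficiency=eff,
                )
            )
        return cls(primers)


@dataclass(frozen=True)
class GenotypeGroup:
    """One genotype arm of the cohort (e.g. ``hom`` with 4 males, 2 females)."""

    label: str
    n_animals: int
    n_male: int
    n_female: int


@dataclass
class CohortDesign:
    """Nested design of a qPCR experiment.

    Animals are nested in litters, measurements in qPCR runs; every
    ``(animal, primer)`` combination is measured in at least one run, in
    ``replicates_per_well`` technical replicates.
    """

    genotypes: list[GenotypeGroup]
    n_litters: int
    n_runs: int
    primers: PrimerMap
    replicates_per_well: int = 3

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise ValidationError("cohort needs at least one genotype group")
        for g in self.genotypes:
            if g.n_male + g.n_female != g.n_animals:
                raise ValidationError(
                    f"genotype {g.label!r}: n_male + n_female != n_animals "
                    f"({g.n_male}+{g.n_female} != {g.n_animals})"
                )
            if g.n_animals < 1:
                raise ValidationError(f"genotype {g.label!r}: needs at least one animal")
        if self.n_litters < 1 or self.n_runs < 1:
            raise ValidationError("n_litters and n_runs must be >= 1")
        if self.replicates_per_well < 1:
            raise ValidationError("replicates_per_well must be >= 1")

    @property
    def genotype_labels(self) -> list[str]:
        return [g.label for g in self.genotypes]

    @property
    def n_animals(self) -> int:
        return sum(g.n_animals for g in self.genotypes)


@dataclass
class GroundTruth:
    """Generative parameters for the Ct simulator.

    The simulated threshold cycle of replicate ``k`` of primer ``p`` in
    animal ``a`` (genotype ``g``, sex ``s``, litter ``l``) measured in run
    ``r`` is

    ``Ct = baseline_ct[p] + genotype_shift[p,g] + sex_shift[p,s]
    + u_r + v_l + w_a + eps``

    with ``u, v, w`` drawn once per run/litter/animal from centred Normals
    with SDs ``sd_run, sd_litter, sd_animal`` and
    ``eps ~ Normal(0, sigma_{p,r})``, ``log sigma_{p,r} = eta0 + eta_primer[p]
    + eta_run[r]``.

    Shifts for the reference genotype/sex default to zero; the true
    cross-genotype ratio-of-ratios is available in closed form via
    :meth:`true_q`.
    """

    baseline_ct: dict[str, float]
    genotype_shift: dict[tuple[str, str], float] = field(default_factory=dict)
    sex_shift: dict[tuple[str, str], float] = field(default_factory=dict)
    sd_run: float = 0.5
    sd_litter: float = 0.3
    sd_animal: float = 0.5
    eta0: float = math.log(0.25)
    eta_primer: dict[str, float] = field(default_factory=dict)
    eta_run: dict[str, float] = field(default_factory=dict)
    efficiency: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, sd in (
            ("sd_run", self.sd_run),
            ("sd_litter", self.sd_litter),
            ("sd_animal", self.sd_animal),
        ):
            if sd < 0:
                raise ValidationError(f"{name} must be >= 0, got {sd}")
        for p, eff in self.efficiency.items():
            if not (1.0 < eff <= 2.0):
                raise ValidationError(f"efficiency for {p!r} outside (1, 2]: {eff}")

    def residual_sd(self, primer: str, run: str) -> float:
        return math.exp(
            self.eta0 + self.eta_primer.get(primer, 0.0) + self.eta_run.get(run, 0.0)
        )

    def shift(self, primer: str, genotype: str) -> float:
        return self.genotype_shift.get((primer, genotype), 0.0)

    def get_efficiency(self, primer: str) -> float:
        return self.efficiency.get(primer, 2.0)

    def true_q(
        self,
        target: str,
        canonical: str,
        genotype_num: str,
        genotype_den: str,
    ) -> float:
        """Closed-form true ratio of (target:canonical) ratios across genotypes.

        Baselines, sex shifts and all varying intercepts cancel; only the
        genotype shifts and the two efficiencies enter:

        ``Q = eff_t^-(shift_t[num]-shift_t[den]) * eff_c^+(shift_c[num]-shift_c[den])``
        """
        dd_t = self.shift(target, genotype_num) - self.shift(target, genotype_den)
        dd_c = self.shift(canonical, genotype_num) - self.shift(canonical, genotype_den)
        q = self.get_efficiency(target) ** (-dd_t) * self.get_efficiency(canonical) ** dd_c
        if not q > 0:
            raise ValidationError("true Q must be > 0")
        return q


@dataclass
class CountSimParams:
    """Parameters of the negative-binomial BSJ / host-gene count simulator."""

    n_samples_per_group: dict[str, int]
    library_size_mean: float = 2.0e7
    library_size_cv: float = 0.2
    nb_dispersion: float = 0.1
    #: per circRNA: (host_gene, baseline counts-per-library, true log2FC mut vs wt)
    circ_baselines: dict[str, tuple[str, float, float]] = field(default_factory=dict)
    #: per host gene: (baseline counts-per-library, true log2FC)
    gene_baselines: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.library_size_mean <= 0:
            raise ValidationError("library_size_mean must be > 0")
        if self.library_size_cv < 0:
            raise ValidationError("library_size_cv must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        for cid, (_, base, _) in self.circ_baselines.items():
            if base < 0:
                raise ValidationError(f"circRNA {cid!r}: baseline must be >= 0")
        for gid, (base, _) in self.gene_baselines.items():
            if base < 0:
                raise ValidationError(f"gene {gid!r}: baseline must be >= 0")


def parse_circ_id(circ_id: str) -> tuple[str, int, int]:
    """Split a ``chrom:start|end`` circRNA id into 1-based inclusive coordinates."""
    try:
        chrom, rest = circ_id.split(":")
        start_s, end_s = rest.split("|")
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ValidationError(
            f"malformed circRNA id {circ_id!r}; expected 'chrom:start|end'"
        ) from None
    if start < 1 or end < start:
        raise ValidationError(f"circRNA id {circ_id!r}: invalid 1-based coordinates")
    return chrom, start, end


@dataclass
class BsjCountTable:
    """Back-spliced-junction read counts (rows: circRNAs, columns: samples).

    ``meta`` carries per-circRNA host gene, 1-based inclusive genomic
    coordinates and strand; ``sample_groups`` maps each sample column to its
    genotype label.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame  # index: circ_id; columns: host_gene, chrom, start, end, strand
    sample_groups: pd.Series  # index: sample, values: genotype

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate circRNA ids")
        missing = set(self.counts.columns) - set(self.sample_groups.index)
        if missing:
            raise ValidationError(f"samples without genotype annotation: {sorted(missing)}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("BSJ counts must be integers")
        if (vals < 0).any():
            raise ValidationError("BSJ counts must be >= 0")
        unmatched = set(self.counts.index) - set(self.meta.index)
        if unmatched:
            raise ValidationError(f"circRNAs without metadata: {sorted(unmatched)}")


@dataclass
class GeneCountTable:
    """Linear-transcript read counts per host gene (rows: genes, cols: samples)."""

    counts: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate gene ids")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("gene counts must be integers")
        if (vals < 0).any():
            raise ValidationError("gene counts must be >= 0")


@dataclass
class RatioEstimate:
    """Posterior summary of a cross-genotype ratio of within-genotype ratios.

    ``excludes_one`` is True iff 1 lies outside the 95% equal-tailed credible
    interval — the significance call used for these estimands.
    """

    target: str
    canonical: str
    genotype_num: str
    genotype_den: str
    mean: float
    geom_mean: float
    ci50: tuple[float, float]
    ci95: tuple[float, float]
    excludes_one: bool
    eff_target: float
    eff_canonical: float

    def __post_init__(self) -> None:
        lo50, hi50 = self.ci50
        lo95, hi95 = self.ci95
        if not (lo95 <= lo50 <= hi50 <= hi95):
            raise ValidationError("50% credible interval must nest inside the 95% interval")

    def to_row(self) -> dict:
        return {
            "target": self.target,
            "canonical": self.canonical,
            "genotype_num": self.genotype_num,
            "genotype_den": self.genotype_den,
            "mean": self.mean,
            "geom_mean": self.geom_mean,
            "ci50_low": self.ci50[0],
            "ci50_high": self.ci50[1],
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "excludes_one": self.excludes_one,
            "eff_target": self.eff_target,
            "eff_canonical": self.eff_canonical,
        }


def validate_ct_frame(df: pd.DataFrame, primer_map: PrimerMap | None = None) -> pd.DataFrame:
    """Check a long-format Ct table against the schema contract.

    Returns the table with canonical column order. Raises
    :class:`ValidationError` listing offending rows on any violation.
    """
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")
    df = df[CT_COLUMNS].copy()
    bad_sex = df.loc[~df["sex"].isin(SEXES)]
    if len(bad_sex):
        raise ValidationError(
            f"invalid sex labels (must be M/F) in rows {bad_sex.index.tolist()[:10]}"
        )
    for col in ("animal", "litter", "genotype", "run", "primer"):
        empties = df.loc[df[col].astype(str).str.len() == 0]
        if len(empties):
            raise ValidationError(f"empty {col} labels in rows {empties.index.tolist()[:10]}")
    if (df["replicate"] < 1).any():
        bad = df.loc[df["replicate"] < 1]
        raise ValidationError(f"replicate_index < 1 in rows {bad.index.tolist()[:10]}")
    detected = df["ct"].notna()
    nonpos = df.loc[detected & (df["ct"] <= 0)]
    if len(nonpos):
        raise ValidationError(f"non-positive Ct in rows {nonpos.index.tolist()[:10]}")
    if primer_map is not None:
        unknown = sorted(set(df["primer"]) - set(primer_map.primer_ids))
        if unknown:
            raise ValidationError(f"unknown primers in Ct table: {unknown}")
    key = ["animal", "primer", "run", "replicate"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise ValidationError(
            f"duplicate (animal, primer, run, replicate) keys, e.g. {tuple(first)}"
        )
    return df
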