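"""Posterior estimands: within-genotype circular:canonical expression
ratios, the cross-genotype ratio of ratios Q, absolute expression relative
to the reference gene, and sensitivity of Q to amplification efficiency.

Under the quantification identity ``E = eff^(−Ct)``, the population-level
ratio of the target:canonical expression ratio between genotypes is

.. math::

    Q = \\mathrm{eff}_t^{-\\Delta\\Delta Ct_t} \\cdot
        \\mathrm{eff}_c^{+\\Delta\\Delta Ct_c}

with ``ΔΔCt_x = E[Ct_x | g_num] − E[Ct_x | g_den]`` computed per posterior
draw. Every term shared between the two species — the reference gene, run,
litter and animal offsets, the sex marginalization — cancels, so Q depends
only on the primer×genotype effects and the two efficiencies; in
particular it is independent of the choice of reference gene. ``Q < 1``
means a lower circular (or alternative-exon) proportion in the numerator
genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PosteriorSamples
from .types import PrimerMap, RatioEstimate, ValidationError


def expected_ct(posterior: PosteriorSamples, primer: str, genotype: str) -> np.ndarray:
    """Posterior draws of the population-level mean Ct of ``primer`` in
    ``genotype``: alpha + beta (0 for the reference genotype) + the equal-
    weight average of the sex effects, with varying intercepts at zero."""
    coords = posterior.coords
    if primer not in coords["primers"]:
        raise ValidationError(f"unknown primer {primer!r}")
    if genotype not in coords["genotypes"]:
        raise ValidationError(f"unknown genotype {genotype!r}")
    out = posterior.get(f"alpha[{primer}]").astype(float).copy()
    if genotype != coords["genotypes"][0]:
        out = out + posterior.get(f"beta[{primer},{genotype}]")
    sexes = coords.get("sexes") or []
    if len(sexes) > 1:
        gamma_sum = np.zeros_like(out)
        for s in sexes[1:]:
            gamma_sum = gamma_sum + posterior.get(f"gamma[{primer},{s}]")
        out = out + gamma_sum / len(sexes)
    return out


def expression_from_ct(ct_draws: np.ndarray, efficiency: float) -> np.ndarray:
    """Relative expression ``eff^(−Ct)`` per draw (arbitrary units)."""
    if not efficiency > 1.0:
        raise ValidationError(f"efficiency must be > 1, got {efficiency}")
    if efficiency > 2.0:
        raise ValidationError(f"efficiency must be <= 2, got {efficiency}")
    return np.asarray(efficiency, dtype=float) ** (-np.asarray(ct_draws, dtype=float))


def _summarize(
    q: np.ndarray,
    target: str,
    canonical: str,
    genotype_num: str,
    genotype_den: str,
    eff_target: float,
    eff_canonical: float,
) -> RatioEstimate:
    if not (q > 0).all():
        raise ValidationError("ratio draws must all be positive")
    lo95, lo50, hi50, hi95 = np.quantile(q, [0.025, 0.25, 0.75, 0.975])
    return RatioEstimate(
        target=target,
        canonical=canonical,
        genotype_num=genotype_num,
        genotype_den=genotype_den,
        mean=float(q.mean()),
        geom_mean=float(np.exp(np.log(q).mean())),
        ci50=(float(lo50), float(hi50)),
        ci95=(float(lo95), float(hi95)),
        excludes_one=bool(hi95 < 1.0 or lo95 > 1.0),
        eff_target=eff_target,
        eff_canonical=eff_canonical,
    )


def ratio_draws(
    posterior: PosteriorSamples,
    target: str,
    canonical: str,
    genotype_num: str,
    genotype_den: str,
    eff_target: float = 2.0,
    eff_canonical: float = 2.0,
) -> np.ndarray:
    """Per-draw Q = eff_t^(−ΔΔCt_t) · eff_c^(+ΔΔCt_c)."""
    dd_t = expected_ct(posterior, target, genotype_num) - expected_ct(
        posterior, target, genotype_den
    )
    dd_c = expected_ct(posterior, canonical, genotype_num) - expected_ct(
        posterior, canonical, genotype_den
    )
    return expression_from_ct(dd_t, eff_target) * (
        1.0 / expression_from_ct(dd_c, eff_canonical)
    )


def ratio_of_ratios(
    posterior: PosteriorSamples,
    target: str,
    canonical: str,
    genotype_num: str,
    genotype_den: str,
    eff_target: float = 2.0,
    eff_canonical: float = 2.0,
    primer_map: PrimerMap | None = None,
) -> RatioEstimate:
    """Cross-genotype ratio of within-genotype target:canonical ratios.

    When a primer map is supplied, ``target`` must be a circular or
    alternative-exon primer and ``canonical`` its paired linear primer.
    Summaries are the posterior mean (the reported point estimate), the
    geometric mean, and equal-tailed 50%/95% credible intervals;
    ``excludes_one`` implements the "95% CI excludes 1" significance call.
    """
    if primer_map is not None:
        t = primer_map[target]
        if t.species_role not in ("circular", "alt_exon"):
            raise ValidationError(
                f"target {target!r} has role {t.species_role!r}; expected circular/alt_exon"
            )
        if t.paired_canonical != canonical:
            raise ValidationError(
                f"{canonical!r} is not the paired canonical primer of {target!r} "
                f"(expected {t.paired_canonical!r})"
            )
    q = ratio_draws(
        posterior, target, canonical, genotype_num, genotype_den, eff_target, eff_canonical
    )
    return _summarize(
        q, target, canonical, genotype_num, genotype_den, eff_target, eff_canonical
    )


def reference_relative_expression(
    posterior: PosteriorSamples,
    target: str,
    reference_primer: str,
    genotype_num: str,
    genotype_den: str,
    eff_target: float = 2.0,
    eff_reference: float = 2.0,
    primer_map: PrimerMap | None = None,
) -> RatioEstimate:
    """Cross-genotype change of a transcript's expression relative to the
    reference gene (absolute-expression estimand): same closed form as
    :func:`ratio_of_ratios` with the canonical primer replaced by the
    reference primer."""
    if primer_map is not None:
        r = primer_map[reference_primer]
        if r.species_role != "reference":
            raise ValidationError(
                f"{reference_primer!r} has role {r.species_role!r}; expected 'reference'"
            )
    q = ratio_draws(
        posterior, target, reference_primer, genotype_num, genotype_den,
        eff_target, eff_reference,
    )
    return _summarize(
        q, target, reference_primer, genotype_num, genotype_den, eff_target, eff_reference
    )


@dataclass
class EfficiencySensitivity:
    """Grid of ratio estimates plus a qualitative-stability verdict."""

    estimates: list[RatioEstimate]
    sign_stable: bool        # sign(log mean Q) identical across the grid
    verdict_stable: bool     # excludes-one call identical across the grid

    @property
    def stable(self) -> bool:
        return self.sign_stable and self.verdict_stable


def efficiency_sensitivity(
    posterior: PosteriorSamples,
    target: str,
    canonical: str,
    genotype_num: str,
    genotype_den: str,
    efficiency_grid,
    primer_map: PrimerMap | None = None,
) -> EfficiencySensitivity:
    """Recompute the ratio of ratios over a grid of efficiency assumptions.

    Grid entries are either single floats (applied to both species) or
    ``(eff_target, eff_canonical)`` pairs; all values must lie in (1, 2].
    """
    grid = list(efficiency_grid)
    if not grid:
        raise ValidationError("empty efficiency grid")
    estimates = []
    for entry in grid:
        if np.isscalar(entry):
            eff_t = eff_c = float(entry)
        else:
            eff_t, eff_c = (float(entry[0]), float(entry[1]))
        estimates.append(
            ratio_of_ratios(
                posterior, target, canonical, genotype_num, genotype_den,
                eff_t, eff_c, primer_map=primer_map,
            )
        )
    signs = {np.sign(np.log(e.mean)) for e in estimates}
    verdicts = {e.excludes_one for e in estimates}
    return EfficiencySensitivity(
        estimates=estimates,
        sign_stable=len(signs) == 1,
        verdict_stable=len(verdicts) == 1,
    )
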