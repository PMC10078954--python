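"""Hierarchical Bayesian model of raw threshold-cycle values.

The observation model is Normal on the Ct scale:

.. math::

    Ct_i \\sim N(\\alpha_{p[i]} + \\beta_{p[i],g[i]} + \\gamma_{p[i],s[i]}
                 + u_{r[i]} + v_{l[i]} + w_{a[i]},\\; \\sigma_{p[i],r[i]})

with fixed effects of primer (``alpha``), primer×genotype (``beta``,
reference genotype pinned at 0) and primer×sex (``gamma``, reference sex
pinned at 0); varying intercepts for qPCR run (``u``), litter (``v``) and
animal (``w``) with half-Normal-prior scales ``tau``; and a log-linear
residual SD ``log sigma = eta0 + eta_primer + eta_run``. Technical
replicates enter as raw observations; the animal intercept absorbs their
biological correlation.

Sampling is a blocked Gibbs scheme: all location parameters are drawn
jointly from their exact multivariate-Normal full conditional, while each
scale parameter is updated by univariate slice sampling in both the
centred and the non-centred (interweaved) parameterization, which avoids
the funnel pathologies that plague single-parameterization samplers of
hierarchical models. Non-detects are excluded by default or upper-censored
at the cycle ceiling via data augmentation.

Convergence is assessed with split R-hat and bulk ESS (arviz); when the
full model fails the gate, varying intercepts are dropped in the order
litter, run and the model is refitted — the fixed-effect structure is
never altered.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .types import ValidationError, validate_ct_frame

_LOG_TAU_MIN, _LOG_TAU_MAX = np.log(1e-4), np.log(1e3)
_TWO_PI = 2.0 * np.pi

RHAT_THRESHOLD = 1.01
ESS_PER_CHAIN = 100


def default_priors() -> dict:
    """Weakly informative defaults on the plausible Ct range (cycles)."""
    return {
        "alpha_mean": 20.0,
        "alpha_sd": 10.0,
        "beta_sd": 5.0,
        "gamma_sd": 5.0,
        "tau_scale": 5.0,
        "eta_sd": 1.0,
    }


@dataclass
class ModelSpec:
    """Structure of the Ct model.

    ``varying_intercepts`` is any subset of ``("run", "litter", "animal")``;
    ``residual_structure`` is ``constant``, ``by_primer`` or
    ``by_primer_and_run``. ``nondetect_policy`` is ``exclude`` (drop
    non-detect wells) or ``censor`` (upper-censor at the cycle ceiling).
    """

    varying_intercepts: tuple[str, ...] = ("run", "litter", "animal")
    residual_structure: str = "by_primer_and_run"
    reference_genotype: str = "wt"
    reference_sex: str = "F"
    nondetect_policy: str = "exclude"
    priors: dict = field(default_factory=default_priors)

    def __post_init__(self) -> None:
        extra = set(self.varying_intercepts) - {"run", "litter", "animal"}
        if extra:
            raise ValidationError(f"unknown varying intercepts: {sorted(extra)}")
        if self.residual_structure not in ("constant", "by_primer", "by_primer_and_run"):
            raise ValidationError(
                f"unknown residual_structure {self.residual_structure!r}"
            )
        if self.nondetect_policy not in ("exclude", "censor"):
            raise ValidationError(f"unknown nondetect_policy {self.nondetect_policy!r}")
        merged = default_priors()
        merged.update(self.priors)
        self.priors = merged

    def without(self, intercept: str) -> "ModelSpec":
        kept = tuple(v for v in self.varying_intercepts if v != intercept)
        return ModelSpec(
            varying_intercepts=kept,
            residual_structure=self.residual_structure,
            reference_genotype=self.reference_genotype,
            reference_sex=self.reference_sex,
            nondetect_policy=self.nondetect_policy,
            priors=dict(self.priors),
        )


@dataclass
class PosteriorSamples:
    """Posterior draws with convergence diagnostics.

    ``params`` maps scalar parameter names (``alpha[primer]``,
    ``beta[primer,genotype]``, ``gamma[primer,sex]``, ``u_run[run]``,
    ``v_litter[litter]``, ``w_animal[animal]``, ``tau_*``, ``eta*``) to
    arrays of shape ``(chains, draws)``. ``coords`` records the factor
    levels, reference levels first for genotype and sex.
    """

    params: dict[str, np.ndarray]
    coords: dict[str, list[str]]
    spec: ModelSpec | None = None
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    fallback_applied: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def get(self, name: str) -> np.ndarray:
        """Flattened draws (all chains concatenated) of one parameter."""
        try:
            return self.params[name].reshape(-1)
        except KeyError:
            raise ValidationError(f"unknown parameter {name!r}") from None

    def draw(self, index: int) -> dict[str, float]:
        """One joint draw as a flat name -> value mapping."""
        c, d = divmod(index, self.n_draws)
        return {k: float(v[c, d]) for k, v in self.params.items()}

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.params.items():
            chains, draws = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(chains), draws),
                        "draw": np.tile(np.arange(draws), chains),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_long_dataframe(
        cls, df: pd.DataFrame, coords: dict | None = None
    ) -> "PosteriorSamples":
        params = {}
        for name, sub in df.groupby("parameter", sort=False):
            chains = int(sub["chain"].max()) + 1
            draws = int(sub["draw"].max()) + 1
            arr = np.full((chains, draws), np.nan)
            arr[sub["chain"].to_numpy(), sub["draw"].to_numpy()] = sub["value"].to_numpy()
            params[name] = arr
        if coords is None:
            coords = _infer_coords(params)
        return cls(params=params, coords=coords)

    def diagnostics_frame(self) -> pd.DataFrame:
        names = sorted(set(self.rhat) | set(self.ess))
        return pd.DataFrame(
            {
                "parameter": names,
                "rhat": [self.rhat.get(n, np.nan) for n in names],
                "ess": [self.ess.get(n, np.nan) for n in names],
            }
        )


def _infer_coords(params: dict[str, np.ndarray]) -> dict[str, list[str]]:
    """Best-effort coords from parameter names (reference levels unknown)."""

    def levels(prefix: str, pos: int = 0) -> list[str]:
        out = []
        for k in params:
            if k.startswith(prefix + "[") and k.endswith("]"):
                inner = k[len(prefix) + 1 : -1].split(",")
                if inner[pos] not in out:
                    out.append(inner[pos])
        return out

    genos = levels("beta", 1)
    sexes = levels("gamma", 1)
    return {
        "primers": levels("alpha"),
        "genotypes": genos,
        "sexes": sexes,
        "runs": levels("u_run"),
        "litters": levels("v_litter"),
        "animals": levels("w_animal"),
    }


# ---------------------------------------------------------------------------
# design assembly


class _Design:
    """Index arrays, dense design matrix and prior vectors for one dataset."""

    def __init__(self, df: pd.DataFrame, spec: ModelSpec, ceiling: float):
        df = validate_ct_frame(df)
        detected = df["ct"].notna()
        if spec.nondetect_policy == "exclude":
            df = df[detected].reset_index(drop=True)
            self.censored = np.zeros(len(df), dtype=bool)
            self.y = df["ct"].to_numpy(dtype=float)
        else:
            df = df.reset_index(drop=True)
            self.censored = df["ct"].isna().to_numpy()
            self.y = np.where(self.censored, ceiling, df["ct"].to_numpy(dtype=float))
        if len(df) == 0:
            raise ValidationError("no detected Ct observations to fit")
        self.ceiling = ceiling
        self.spec = spec

        self.primers = sorted(df["primer"].unique())
        genos = sorted(df["genotype"].unique())
        if spec.reference_genotype not in genos:
            raise ValidationError(
                f"reference genotype {spec.reference_genotype!r} not present in data"
            )
        if len(genos) < 2:
            raise ValidationError("need at least two genotypes to fit")
        self.genotypes = [spec.reference_genotype] + [
            g for g in genos if g != spec.reference_genotype
        ]
        sexes = sorted(df["sex"].unique())
        self.sexes = (
            [spec.reference_sex] + [s for s in sexes if s != spec.reference_sex]
            if spec.reference_sex in sexes
            else sexes
        )
        self.runs = sorted(df["run"].unique())
        self.litters = sorted(df["litter"].unique())
        self.animals = sorted(df["animal"].unique())

        counts = df.groupby("primer").size()
        lonely = counts[counts < 2]
        if len(lonely):
            raise ValidationError(
                f"degenerate data: primer {lonely.index[0]!r} has a single observation"
            )
        cells = df.groupby(["primer", "genotype"]).size()
        for p in self.primers:
            for g in self.genotypes:
                if (p, g) not in cells.index:
                    raise ValidationError(
                        f"fixed-effect level unobserved: primer {p!r} x genotype {g!r}"
                    )

        def codes(col, levels):
            m = {lvl: i for i, lvl in enumerate(levels)}
            return df[col].map(m).to_numpy(dtype=np.intp)

        self.primer_idx = codes("primer", self.primers)
        self.geno_idx = codes("genotype", self.genotypes)
        self.sex_idx = codes("sex", self.sexes)
        self.run_idx = codes("run", self.runs)
        self.litter_idx = codes("litter", self.litters)
        self.animal_idx = codes("animal", self.animals)

        n = len(df)
        P, G, S = len(self.primers), len(self.genotypes), len(self.sexes)
        cols: list[str] = []
        blocks: dict[str, slice] = {}

        def add_block(name, labels):
            start = len(cols)
            cols.extend(labels)
            blocks[name] = slice(start, len(cols))

        add_block("alpha", [f"alpha[{p}]" for p in self.primers])
        add_block(
            "beta",
            [f"beta[{p},{g}]" for g in self.genotypes[1:] for p in self.primers],
        )
        add_block(
            "gamma",
            [f"gamma[{p},{s}]" for s in self.sexes[1:] for p in self.primers],
        )
        self.re_group_idx: dict[str, np.ndarray] = {}
        if "run" in spec.varying_intercepts:
            add_block("u", [f"u_run[{r}]" for r in self.runs])
            self.re_group_idx["run"] = self.run_idx
        if "litter" in spec.varying_intercepts:
            add_block("v", [f"v_litter[{l}]" for l in self.litters])
            self.re_group_idx["litter"] = self.litter_idx
        if "animal" in spec.varying_intercepts:
            add_block("w", [f"w_animal[{a}]" for a in self.animals])
            self.re_group_idx["animal"] = self.animal_idx

        self.col_names = cols
        self.blocks = blocks
        K = len(cols)
        X = np.zeros((n, K), dtype=float)
        rows = np.arange(n)
        X[rows, self.primer_idx] = 1.0
        nonref_g = self.geno_idx > 0
        X[rows[nonref_g], P + (self.geno_idx[nonref_g] - 1) * P + self.primer_idx[nonref_g]] = 1.0
        off = P + (G - 1) * P
        nonref_s = self.sex_idx > 0
        X[rows[nonref_s], off + (self.sex_idx[nonref_s] - 1) * P + self.primer_idx[nonref_s]] = 1.0
        off += (S - 1) * P
        for key, blk in (("run", "u"), ("litter", "v"), ("animal", "w")):
            if blk in blocks:
                sl = blocks[blk]
                X[rows, sl.start + self.re_group_idx[key]] = 1.0
        self.X = X

        pr = spec.priors
        self.prior_mean = np.zeros(K)
        self.prior_mean[blocks["alpha"]] = pr["alpha_mean"]
        self.prior_sd = np.empty(K)
        self.prior_sd[blocks["alpha"]] = pr["alpha_sd"]
        self.prior_sd[blocks["beta"]] = pr["beta_sd"]
        self.prior_sd[blocks["gamma"]] = pr["gamma_sd"]
        # u/v/w prior SDs are the taus, filled in per sweep

        self.re_block_name = {"run": "u", "litter": "v", "animal": "w"}

    @property
    def n_obs(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------------
# slice sampler


def _slice_sample(logf, x0, rng, w=1.0, max_steps=30, lo=-np.inf, hi=np.inf):
    """Univariate slice sampling with stepping-out and shrinkage (Neal 2003)."""
    f0 = logf(x0)
    log_y = f0 + np.log(rng.uniform(1e-300, 1.0))
    left = x0 - w * rng.uniform()
    right = left + w
    j = int(max_steps * rng.uniform())
    k = max_steps - 1 - j
    while j > 0 and left > lo and logf(max(left, lo)) > log_y:
        left -= w
        j -= 1
    while k > 0 and right < hi and logf(min(right, hi)) > log_y:
        right += w
        k -= 1
    left, right = max(left, lo), min(right, hi)
    for _ in range(100):
        x1 = rng.uniform(left, right)
        if logf(x1) > log_y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


# ---------------------------------------------------------------------------
# likelihood pieces


def _log_sigma_obs(design: _Design, eta0, eta_p, eta_r):
    s = np.full(design.n_obs, eta0)
    if design.spec.residual_structure in ("by_primer", "by_primer_and_run"):
        s = s + eta_p[design.primer_idx]
    if design.spec.residual_structure == "by_primer_and_run":
        s = s + eta_r[design.run_idx]
    return s


def ct_log_density(
    record,
    params: dict,
    reference_genotype: str = "wt",
    reference_sex: str = "F",
    residual_structure: str = "by_primer_and_run",
) -> float:
    """Normal log-density of one detected Ct record under one parameter draw.

    ``params`` is a flat draw as produced by :meth:`PosteriorSamples.draw`.
    Levels absent from the draw (for parameter families the draw contains)
    are rejected.
    """
    p, g, s = record["primer"], record["genotype"], record["sex"]
    ct = record["ct"]
    if ct is None or (isinstance(ct, float) and np.isnan(ct)):
        raise ValidationError("ct_log_density requires a detected Ct")

    def fetch(name: str, family: str) -> float:
        if name in params:
            return params[name]
        if any(k.startswith(family + "[") for k in params):
            raise ValidationError(f"unknown level: no parameter {name!r} in draw")
        return 0.0

    mu = fetch(f"alpha[{p}]", "alpha")
    if f"alpha[{p}]" not in params:
        raise ValidationError(f"unknown primer {p!r}")
    if g != reference_genotype:
        if f"beta[{p},{g}]" not in params:
            raise ValidationError(f"unknown level: genotype {g!r} for primer {p!r}")
        mu += params[f"beta[{p},{g}]"]
    if s != reference_sex:
        if f"gamma[{p},{s}]" not in params:
            raise ValidationError(f"unknown level: sex {s!r} for primer {p!r}")
        mu += params[f"gamma[{p},{s}]"]
    mu += fetch(f"u_run[{record['run']}]", "u_run")
    mu += fetch(f"v_litter[{record['litter']}]", "v_litter")
    mu += fetch(f"w_animal[{record['animal']}]", "w_animal")

    log_sigma = params.get("eta0", 0.0)
    if residual_structure in ("by_primer", "by_primer_and_run"):
        log_sigma += fetch(f"eta_primer[{p}]", "eta_primer")
    if residual_structure == "by_primer_and_run":
        log_sigma += fetch(f"eta_run[{record['run']}]", "eta_run")
    sigma = np.exp(log_sigma)
    return float(-0.5 * np.log(_TWO_PI) - log_sigma - 0.5 * ((ct - mu) / sigma) ** 2)


# ---------------------------------------------------------------------------
# the sampler


def _run_chain(design: _Design, n_keep: int, warmup: int, rng: np.random.Generator):
    spec = design.spec
    pr = spec.priors
    K = len(design.col_names)
    P, R = len(design.primers), len(design.runs)
    y = design.y.copy()

    n_fixed = design.blocks["gamma"].stop
    Xf = design.X[:, :n_fixed]
    U = design.X[:, n_fixed:]
    re_order = list(design.re_group_idx)  # insertion order: run, litter, animal
    col_re = np.concatenate(
        [
            np.full(design.blocks[design.re_block_name[re]].stop
                    - design.blocks[design.re_block_name[re]].start, i)
            for i, re in enumerate(re_order)
        ]
    ) if re_order else np.empty(0, dtype=int)

    # --- initial values
    theta = np.zeros(K)
    asl = design.blocks["alpha"]
    for i, p in enumerate(design.primers):
        mask = design.primer_idx == i
        theta[asl.start + i] = y[mask].mean()
    theta += rng.normal(0.0, 0.1, size=K)
    taus = {re: float(abs(rng.normal(0.3, 0.1)) + 0.05) for re in design.re_group_idx}
    resid0 = y - theta[design.primer_idx]
    s0 = max(float(np.std(resid0)), 0.05)
    eta0 = float(np.log(s0) + rng.normal(0.0, 0.1))
    eta_p = rng.normal(0.0, 0.05, size=P)
    eta_r = rng.normal(0.0, 0.05, size=R)
    if spec.residual_structure == "constant":
        eta_p[:] = 0.0
        eta_r[:] = 0.0
    elif spec.residual_structure == "by_primer":
        eta_r[:] = 0.0

    keep_theta = np.empty((n_keep, K))
    keep_tau = {re: np.empty(n_keep) for re in taus}
    keep_eta0 = np.empty(n_keep)
    keep_eta_p = np.empty((n_keep, P))
    keep_eta_r = np.empty((n_keep, R))

    X = design.X
    eta_sd = pr["eta_sd"]
    tau_scale = pr["tau_scale"]
    any_cens = design.censored.any()
    eye_m = np.eye(U.shape[1]) if U.shape[1] else None

    for it in range(warmup + n_keep):
        log_sig = _log_sigma_obs(design, eta0, eta_p, eta_r)
        sigma = np.exp(log_sig)
        w_prec = 1.0 / sigma**2

        if any_cens:
            mu_full = X @ theta
            cz = design.censored
            a = (design.ceiling - mu_full[cz]) / sigma[cz]
            y[cz] = _st.truncnorm.rvs(
                a, np.inf, loc=mu_full[cz], scale=sigma[cz], random_state=rng
            )

        # --- variance scales, fully collapsed: slice-sample each tau from
        # the marginal likelihood with ALL varying intercepts integrated
        # out (Woodbury through the (R+L+A)-dim capacitance matrix). The
        # intercepts themselves are redrawn immediately afterwards in the
        # joint location step, so no stale values are ever reused.
        if re_order:
            r0 = y - Xf @ theta[:n_fixed]
            A0 = (U * w_prec[:, None]).T @ U
            g = U.T @ (w_prec * r0)
            s_col = np.array([taus[re_order[i]] for i in col_re])

            def marginal_loglik(s_vec):
                C = eye_m + (s_vec[:, None] * s_vec[None, :]) * A0
                Lc = cholesky(C, lower=True)
                b = s_vec * g
                half = solve_triangular(Lc, b, lower=True)
                return 0.5 * float(half @ half) - float(
                    np.sum(np.log(np.diag(Lc)))
                )

            for i, re in enumerate(re_order):
                mask = col_re == i

                def logp_tau(zt):
                    t = np.exp(zt)
                    s_try = s_col.copy()
                    s_try[mask] = t
                    return (
                        marginal_loglik(s_try)
                        - 0.5 * (t / tau_scale) ** 2
                        + zt
                    )

                zt = _slice_sample(
                    logp_tau, np.log(taus[re]), rng, w=1.0,
                    lo=_LOG_TAU_MIN, hi=_LOG_TAU_MAX,
                )
                taus[re] = float(np.exp(zt))
                s_col[mask] = taus[re]

        # --- joint draw of all location parameters given the new scales
        prior_sd = design.prior_sd.copy()
        for re, tau in taus.items():
            sl = design.blocks[design.re_block_name[re]]
            prior_sd[sl] = max(tau, 1e-4)
        Xw = X * w_prec[:, None]
        prec = X.T @ Xw
        prec[np.diag_indices_from(prec)] += 1.0 / prior_sd**2
        b = Xw.T @ y + design.prior_mean / prior_sd**2
        Lc = cholesky(prec, lower=True)
        mean = cho_solve((Lc, True), b)
        z = rng.standard_normal(K)
        theta = mean + solve_triangular(Lc.T, z, lower=False)

        # --- residual SD parameters
        resid = y - X @ theta
        base_off = np.zeros(design.n_obs)
        if spec.residual_structure in ("by_primer", "by_primer_and_run"):
            base_off += eta_p[design.primer_idx]
        if spec.residual_structure == "by_primer_and_run":
            base_off += eta_r[design.run_idx]

        def lik(log_sig_vec, r):
            return float(np.sum(-log_sig_vec - 0.5 * (r / np.exp(log_sig_vec)) ** 2))

        def logp_eta0(e):
            return -0.5 * (e / eta_sd) ** 2 + lik(e + base_off, resid)

        eta0 = _slice_sample(logp_eta0, eta0, rng, w=0.5, lo=-12.0, hi=6.0)

        if spec.residual_structure in ("by_primer", "by_primer_and_run"):
            for i in range(P):
                mask = design.primer_idx == i
                r_i = resid[mask]
                other = eta0 + (
                    eta_r[design.run_idx[mask]]
                    if spec.residual_structure == "by_primer_and_run"
                    else 0.0
                )

                def logp(e):
                    return -0.5 * (e / eta_sd) ** 2 + lik(other + e, r_i)

                eta_p[i] = _slice_sample(logp, eta_p[i], rng, w=0.5, lo=-8.0, hi=8.0)
        if spec.residual_structure == "by_primer_and_run":
            for i in range(R):
                mask = design.run_idx == i
                r_i = resid[mask]
                other = eta0 + eta_p[design.primer_idx[mask]]

                def logp(e):
                    return -0.5 * (e / eta_sd) ** 2 + lik(other + e, r_i)

                eta_r[i] = _slice_sample(logp, eta_r[i], rng, w=0.5, lo=-8.0, hi=8.0)

        # exact recentring between eta0 and the eta_p / eta_r offsets: the
        # likelihood depends only on their sums, so the shift d has a
        # Gaussian full conditional under the Normal priors
        if spec.residual_structure in ("by_primer", "by_primer_and_run"):
            d = rng.normal(
                (eta_p.sum() - eta0) / (1 + P), eta_sd / np.sqrt(1 + P)
            )
            eta0 += d
            eta_p -= d
        if spec.residual_structure == "by_primer_and_run":
            d = rng.normal(
                (eta_r.sum() - eta0) / (1 + R), eta_sd / np.sqrt(1 + R)
            )
            eta0 += d
            eta_r -= d

        if it >= warmup:
            k = it - warmup
            keep_theta[k] = theta
            for re in taus:
                keep_tau[re][k] = taus[re]
            keep_eta0[k] = eta0
            keep_eta_p[k] = eta_p
            keep_eta_r[k] = eta_r

    return keep_theta, keep_tau, keep_eta0, keep_eta_p, keep_eta_r


def _diagnose(params: dict[str, np.ndarray]) -> tuple[dict, dict]:
    import arviz as az

    ds = az.convert_to_dataset({k: v for k, v in params.items()})
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        rh = az.rhat(ds)
        es = az.ess(ds, method="bulk")
    rhat = {k: float(rh[k].values) for k in params}
    ess = {k: float(es[k].values) for k in params}
    return rhat, ess


def _gate(posterior: PosteriorSamples, chains: int) -> tuple[bool, list[str]]:
    """Convergence gate on population-level parameters."""
    problems = []
    for name in posterior.params:
        if not name.startswith(("alpha", "beta", "gamma", "tau", "eta0")):
            continue
        rh = posterior.rhat.get(name, np.nan)
        es = posterior.ess.get(name, np.nan)
        if np.isfinite(rh) and rh >= RHAT_THRESHOLD:
            problems.append(f"R-hat {rh:.3f} for {name}")
        elif np.isfinite(es) and es < ESS_PER_CHAIN * chains:
            problems.append(f"ESS {es:.0f} for {name}")
    return (len(problems) == 0), problems


def _fit_once(
    df: pd.DataFrame,
    spec: ModelSpec,
    seed: int,
    chains: int,
    draws: int,
    warmup: int,
    ceiling: float,
) -> PosteriorSamples:
    design = _Design(df, spec, ceiling)
    children = np.random.SeedSequence(seed).spawn(chains)
    all_theta = np.empty((chains, draws, len(design.col_names)))
    all_tau = {re: np.empty((chains, draws)) for re in design.re_group_idx}
    all_eta0 = np.empty((chains, draws))
    all_eta_p = np.empty((chains, draws, len(design.primers)))
    all_eta_r = np.empty((chains, draws, len(design.runs)))
    for c in range(chains):
        rng = np.random.default_rng(children[c])
        th, tau, e0, ep, er = _run_chain(design, draws, warmup, rng)
        all_theta[c] = th
        for re in tau:
            all_tau[re][c] = tau[re]
        all_eta0[c] = e0
        all_eta_p[c] = ep
        all_eta_r[c] = er

    params: dict[str, np.ndarray] = {}
    for j, name in enumerate(design.col_names):
        params[name] = all_theta[:, :, j]
    for re in all_tau:
        params[f"tau_{re}"] = all_tau[re]
    params["eta0"] = all_eta0
    if spec.residual_structure in ("by_primer", "by_primer_and_run"):
        for i, p in enumerate(design.primers):
            params[f"eta_primer[{p}]"] = all_eta_p[:, :, i]
    if spec.residual_structure == "by_primer_and_run":
        for i, r in enumerate(design.runs):
            params[f"eta_run[{r}]"] = all_eta_r[:, :, i]

    rhat, ess = _diagnose(params)
    coords = {
        "primers": design.primers,
        "genotypes": design.genotypes,
        "sexes": design.sexes,
        "runs": design.runs,
        "litters": design.litters,
        "animals": design.animals,
    }
    post = PosteriorSamples(
        params=params, coords=coords, spec=spec, rhat=rhat, ess=ess
    )
    ok, problems = _gate(post, chains)
    post.converged = ok
    if not ok:
        post.warnings.extend(problems)
    return post


def fit(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    seed: int = 0,
    chains: int = 4,
    draws: int = 500,
    warmup: int = 300,
    ceiling: float = 40.0,
    allow_fallback: bool = True,
) -> PosteriorSamples:
    """Fit the hierarchical Ct model by blocked Gibbs sampling.

    ``draws`` are post-warmup draws per chain; ``chains * draws`` must be at
    least 400. Identical ``(seed, chains, draws)`` give identical draws.
    When the convergence gate (split R-hat < 1.01 and bulk ESS ≥ 100 per
    chain on population-level parameters) fails and ``allow_fallback`` is
    set, varying intercepts are dropped in the order litter, run and the
    model refitted; the event is recorded in ``warnings`` and
    ``fallback_applied``. Fixed effects are never dropped.
    """
    spec = spec or ModelSpec()
    if chains < 2:
        raise ValidationError("need at least 2 chains for split R-hat")
    if chains * draws < 400:
        raise ValidationError("need at least 400 post-warmup draws in total")

    attempts = [spec]
    reduced = spec
    for drop in ("litter", "run"):
        if drop in reduced.varying_intercepts:
            reduced = reduced.without(drop)
            attempts.append(reduced)

    history: list[str] = []
    post = None
    for i, sp in enumerate(attempts):
        post = _fit_once(data, sp, seed, chains, draws, warmup, ceiling)
        post.fallback_applied = i > 0
        post.warnings = history + post.warnings
        if post.converged or not allow_fallback:
            break
        dropped = set(sp.varying_intercepts) - set(
            attempts[i + 1].varying_intercepts if i + 1 < len(attempts) else ()
        )
        if i + 1 < len(attempts):
            history.append(
                f"convergence gate failed for varying intercepts {sp.varying_intercepts}; "
                f"dropping {sorted(dropped)} and refitting"
            )
    if post is not None and not post.converged:
        _warnings.warn(
            "model did not pass the convergence gate: " + "; ".join(post.warnings),
            UserWarning,
            stacklevel=2,
        )
    return post


# ---------------------------------------------------------------------------
# posterior predictive checking


_DEFAULT_PPC_STATS = ("sd_by_primer", "sd_by_run", "min", "max")


def _stack_params(posterior: PosteriorSamples, picks: np.ndarray):
    """Selected draws of every parameter family as dense arrays.

    Returns dict with arrays over (selected draw, level...) where absent
    reference-level effects are zero."""
    coords = posterior.coords
    flat = {k: v.reshape(-1)[picks] for k, v in posterior.params.items()}
    S = len(picks)

    def grab(fmt, levels, default_zero=True):
        out = np.zeros((S, len(levels)))
        for j, lvl in enumerate(levels):
            name = fmt.format(lvl)
            if name in flat:
                out[:, j] = flat[name]
            elif not default_zero:
                raise ValidationError(f"missing parameter {name!r}")
        return out

    P = coords["primers"]
    G = coords["genotypes"]
    Sx = coords["sexes"]
    beta = np.zeros((S, len(P), len(G)))
    gamma = np.zeros((S, len(P), max(len(Sx), 1)))
    for ip, p in enumerate(P):
        for ig, g in enumerate(G[1:], start=1):
            beta[:, ip, ig] = flat.get(f"beta[{p},{g}]", 0.0)
        for isx, s in enumerate(Sx[1:], start=1):
            gamma[:, ip, isx] = flat.get(f"gamma[{p},{s}]", 0.0)
    return {
        "alpha": grab("alpha[{}]", P, default_zero=False),
        "beta": beta,
        "gamma": gamma,
        "u": grab("u_run[{}]", coords.get("runs", [])),
        "v": grab("v_litter[{}]", coords.get("litters", [])),
        "w": grab("w_animal[{}]", coords.get("animals", [])),
        "eta0": flat.get("eta0", np.zeros(S)),
        "eta_p": grab("eta_primer[{}]", P),
        "eta_r": grab("eta_run[{}]", coords.get("runs", [])),
    }


def _codes_against(df: pd.DataFrame, col: str, levels: list[str]) -> np.ndarray:
    lut = {lvl: i for i, lvl in enumerate(levels)}
    unknown = sorted(set(df[col]) - set(lut))
    if unknown:
        raise ValidationError(f"unknown {col} level(s) {unknown} for this posterior")
    return df[col].map(lut).to_numpy(dtype=np.intp)


def posterior_predictive_draws(
    data: pd.DataFrame,
    posterior: PosteriorSamples,
    n: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """``n`` replicated Ct datasets from the posterior predictive.

    Returns the detected-observation frame the replicates align with and an
    ``(n, n_obs)`` array of replicated Ct values. Varying intercepts are
    taken from their posterior draws (same grouping units as the data).
    """
    df = validate_ct_frame(data)
    df = df[df["ct"].notna()].reset_index(drop=True)
    coords = posterior.coords
    total = posterior.n_chains * posterior.n_draws
    picks = np.linspace(0, total - 1, num=min(n, total), dtype=int)
    pars = _stack_params(posterior, picks)

    p_idx = _codes_against(df, "primer", coords["primers"])
    g_idx = _codes_against(df, "genotype", coords["genotypes"])
    s_idx = (
        _codes_against(df, "sex", coords["sexes"])
        if coords.get("sexes")
        else np.zeros(len(df), dtype=np.intp)
    )
    mu = pars["alpha"][:, p_idx] + pars["beta"][:, p_idx, g_idx] + pars["gamma"][:, p_idx, s_idx]
    log_sig = pars["eta0"][:, None] + np.zeros((1, len(df)))
    structure = (posterior.spec.residual_structure if posterior.spec
                 else "by_primer_and_run")
    if pars["eta_p"].shape[1]:
        log_sig = log_sig + pars["eta_p"][:, p_idx]
    for key, col, lut_key in (("u", "run", "runs"), ("v", "litter", "litters"),
                              ("w", "animal", "animals")):
        if pars[key].shape[1]:
            idx = _codes_against(df, col, coords[lut_key])
            mu = mu + pars[key][:, idx]
    if pars["eta_r"].shape[1] and structure == "by_primer_and_run":
        r_idx = _codes_against(df, "run", coords["runs"])
        log_sig = log_sig + pars["eta_r"][:, r_idx]
    rng = np.random.default_rng(seed)
    out = rng.normal(mu, np.exp(log_sig))
    return df, out


def _compute_stats(df: pd.DataFrame, y: np.ndarray, statistics) -> dict[tuple[str, str], float]:
    vals: dict[tuple[str, str], float] = {}
    for stat in statistics:
        if stat == "sd_by_primer":
            for p in sorted(df["primer"].unique()):
                mask = (df["primer"] == p).to_numpy()
                vals[("sd_by_primer", p)] = float(np.std(y[mask], ddof=1))
        elif stat == "sd_by_run":
            for r in sorted(df["run"].unique()):
                mask = (df["run"] == r).to_numpy()
                vals[("sd_by_run", r)] = float(np.std(y[mask], ddof=1))
        elif stat == "min":
            vals[("min", "")] = float(y.min())
        elif stat == "max":
            vals[("max", "")] = float(y.max())
        else:
            raise ValidationError(f"unknown PPC statistic {stat!r}")
    return vals


def posterior_predictive_check(
    data: pd.DataFrame,
    posterior: PosteriorSamples,
    statistics: tuple[str, ...] = _DEFAULT_PPC_STATS,
    n_rep: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank each observed summary statistic within its posterior-predictive
    replicate distribution; extreme ranks (<2.5% or >97.5%) are flagged.

    A well-calibrated model flags ≈5% of statistics when the data really
    come from it; systematic flags (e.g. observed per-primer SD always at
    low rank) indicate over-estimated variability.
    """
    if not statistics:
        raise ValidationError("empty statistic list")
    df, reps = posterior_predictive_draws(data, posterior, n_rep, seed=seed)
    y_obs = df["ct"].to_numpy(dtype=float)
    obs = _compute_stats(df, y_obs, statistics)
    rep_vals: dict[tuple[str, str], list[float]] = {k: [] for k in obs}
    for j in range(reps.shape[0]):
        sv = _compute_stats(df, reps[j], statistics)
        for k, v in sv.items():
            rep_vals[k].append(v)
    rows = []
    for (stat, group), o in obs.items():
        rv = np.asarray(rep_vals[(stat, group)])
        rank = (np.sum(rv < o) + 0.5 * np.sum(rv == o)) / len(rv)
        rows.append(
            {
                "statistic": stat,
                "group": group,
                "observed": o,
                "rank_prop": rank,
                "flagged": bool(rank < 0.025 or rank > 0.975),
            }
        )
    return pd.DataFrame(rows)
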