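"""Default g-prior Bayes factors for the within-subject PSE design.

The model family is the standard default ANOVA construction: observations
``y = mu*1 + sum_j X_j theta_j + eps`` with a flat prior on the grand mean
``mu``, Jeffreys prior on the error variance ``sigma^2``, and for each
effect family j (eyeshadow, orientation, their interaction, subject) a
g-prior ``theta_j | g_j ~ N(0, g_j sigma^2 I)`` on sum-to-zero coded,
orthonormal-contrast effects.  Each ``g_j`` carries a scaled
inverse-chi-square prior with one degree of freedom and scale ``r^2``,
with ``r = 1/2`` for fixed-effect families and ``r = 1`` for the subject
(random) family — the defaults of the common Bayesian-ANOVA software.

Conditional on the g vector, the marginal likelihood is available in
closed form because the balanced factorial design makes the family design
matrices mutually orthogonal.  The remaining low-dimensional integral
over the g's is done by seeded importance sampling with a defensive
mixture proposal (Laplace approximation mixed with the prior), or by
deterministic grid quadrature for models with at most two g dimensions.

Null-model conventions: a main effect is tested against the
intercept-plus-subject model; the interaction is tested against the model
containing both main effects (and subject) but no interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.special import gammaln, logsumexp

from .anova import orthonormal_contrast
from .pse import PSETable

__all__ = [
    "BFModelSpec",
    "BayesFactorResult",
    "EFFECTS",
    "build_design",
    "conditional_marginal_likelihood",
    "model_log_marginal",
    "compare_models",
    "bayes_factor",
    "interpret_bf",
]

EFFECTS = ("shadow", "orientation", "interaction")

#: Relative Monte-Carlo error above which a BF result is flagged.
MC_ERROR_THRESHOLD = 0.05
#: Defensive mixture weight on the prior component of the IS proposal.
PRIOR_MIXTURE_WEIGHT = 0.3
#: Variance inflation of the Laplace component of the IS proposal.
PROPOSAL_SCALE = 2.0
#: Grid half-width (in posterior SDs) and points per dimension for the
#: quadrature fallback.
QUAD_HALF_WIDTH = 12.0
QUAD_POINTS = 401


@dataclass(frozen=True)
class BFModelSpec:
    """One linear model of the PSE table, named by its fixed effects.

    ``fixed_effects`` is a subset of ``{"shadow", "orientation",
    "interaction"}``; the interaction may only appear together with both
    main effects.  The subject family is always present as a random
    effect.  ``r_fixed`` and ``r_random`` are the g-prior scales.
    """

    fixed_effects: tuple[str, ...] = ()
    random_effects: tuple[str, ...] = ("subject",)
    r_fixed: float = 0.5
    r_random: float = 1.0

    def __post_init__(self) -> None:
        unknown = set(self.fixed_effects) - set(EFFECTS)
        if unknown:
            raise ValueError(f"unknown fixed effects: {sorted(unknown)}")
        if "interaction" in self.fixed_effects and not (
            "shadow" in self.fixed_effects
            and "orientation" in self.fixed_effects
        ):
            raise ValueError(
                "interaction requires both main effects in the model"
            )
        if self.random_effects != ("subject",):
            raise ValueError("the only supported random effect is 'subject'")
        if self.r_fixed <= 0 or self.r_random <= 0:
            raise ValueError("prior r scales must be > 0")

    @property
    def families(self) -> tuple[str, ...]:
        """Effect families in canonical order (fixed first, then subject)."""
        fixed = tuple(e for e in EFFECTS if e in self.fixed_effects)
        return fixed + ("subject",)

    def r_scale(self, family: str) -> float:
        return self.r_random if family == "subject" else self.r_fixed


@dataclass(frozen=True)
class _Family:
    name: str
    x: np.ndarray  # N x p design block, orthonormal level contrasts
    p: int
    c: float  # X'X = c * I in the balanced design


@dataclass(frozen=True)
class _Design:
    """Centered data vector plus sufficient statistics per family."""

    y_centered: np.ndarray
    n_obs: int
    families: Mapping[str, _Family]
    yty: float  # ||y - ybar||^2
    uu: Mapping[str, float]  # ||X_j' y||^2 per family


def build_design(table: PSETable) -> _Design:
    """Effect-coded design blocks and sufficient statistics for a table.

    Rows are ordered subject-major, then shadow, then angle.  Factors
    with a single level contribute no family.  Mutual orthogonality of
    the family blocks (guaranteed by the balanced design) is verified.
    """
    wide = table.to_wide()  # (n, a, b)
    n, a, b = wide.shape
    y = wide.reshape(-1)
    n_obs = y.size
    rows = np.arange(n_obs)
    subj_idx = rows // (a * b)
    shadow_idx = (rows // b) % a
    angle_idx = rows % b
    cell_idx = shadow_idx * b + angle_idx

    def family(name: str, codes: np.ndarray, q: np.ndarray) -> _Family:
        x = q[codes, :]
        gram = x.T @ x
        c = float(gram[0, 0])
        if not np.allclose(gram, c * np.eye(gram.shape[1]), atol=1e-8):
            raise ValueError(f"family {name} is not balanced-orthogonal")
        return _Family(name=name, x=x, p=x.shape[1], c=c)

    fams: dict[str, _Family] = {}
    if a >= 2:
        fams["shadow"] = family("shadow", shadow_idx, orthonormal_contrast(a))
    if b >= 2:
        fams["orientation"] = family(
            "orientation", angle_idx, orthonormal_contrast(b)
        )
    if a >= 2 and b >= 2:
        fams["interaction"] = family(
            "interaction",
            cell_idx,
            np.kron(orthonormal_contrast(a), orthonormal_contrast(b)),
        )
    fams["subject"] = family("subject", subj_idx, orthonormal_contrast(n))

    # cross-family orthogonality (holds for any complete balanced layout)
    names = list(fams)
    for i, ni in enumerate(names):
        for nj in names[i + 1:]:
            if not np.allclose(fams[ni].x.T @ fams[nj].x, 0.0, atol=1e-8):
                raise ValueError(f"families {ni} and {nj} not orthogonal")

    yc = y - y.mean()
    uu = {name: float(np.sum((f.x.T @ yc) ** 2)) for name, f in fams.items()}
    return _Design(
        y_centered=yc,
        n_obs=n_obs,
        families=fams,
        yty=float(yc @ yc),
        uu=uu,
    )


def _check_spec_available(design: _Design, spec: BFModelSpec) -> list[str]:
    names = list(spec.families)
    missing = [f for f in names if f not in design.families]
    if missing:
        raise ValueError(
            f"model requires effect families absent from the data: {missing}"
        )
    return names


def _conditional_logm(
    design: _Design, names: Sequence[str], g: np.ndarray
) -> np.ndarray:
    """Closed-form log m(y | g); vectorized over rows of ``g``.

    With mutually orthogonal families and X_j'X_j = c_j I:

        m(y|g) = Gamma((N-1)/2) * pi^(-(N-1)/2) * N^(-1/2)
                 * prod_j (1 + g_j c_j)^(-p_j/2) * Q(g)^(-(N-1)/2)
        Q(g)   = ||yc||^2 - sum_j g_j c_j / (1 + g_j c_j) * ||X_j'yc||^2 / c_j

    obtained by integrating the effects (normal), the grand mean (flat)
    and the error variance (Jeffreys) analytically.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    if np.any(g < 0):
        raise ValueError("g values must be >= 0")
    n_obs = design.n_obs
    c = np.array([design.families[f].c for f in names])
    p = np.array([design.families[f].p for f in names])
    uu = np.array([design.uu[f] for f in names])
    gc = g * c  # (rows, J)
    logdet = np.sum(p * np.log1p(gc), axis=1)
    q = design.yty - np.sum(gc / (1.0 + gc) * (uu / c), axis=1)
    out = (
        gammaln((n_obs - 1) / 2.0)
        - (n_obs - 1) / 2.0 * math.log(math.pi)
        - 0.5 * math.log(n_obs)
        - 0.5 * logdet
        - (n_obs - 1) / 2.0 * np.log(q)
    )
    return out


def conditional_marginal_likelihood(
    table: PSETable,
    spec: BFModelSpec,
    g_values: Sequence[float] | Mapping[str, float],
) -> float:
    """Exact log marginal likelihood of ``spec`` given fixed g values.

    ``g_values`` is either a mapping family name -> g or a sequence in
    ``spec.families`` order.
    """
    design = build_design(table)
    names = _check_spec_available(design, spec)
    if isinstance(g_values, Mapping):
        g = np.array([g_values[f] for f in names], dtype=float)
    else:
        g = np.asarray(list(g_values), dtype=float)
        if g.size != len(names):
            raise ValueError(
                f"expected {len(names)} g values ({names}), got {g.size}"
            )
    return float(_conditional_logm(design, names, g)[0])


def _log_prior_z(z: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Log density of z = log g under scaled-inv-chi-square(1, r^2) on g."""
    # g ~ InvGamma(1/2, r^2/2); p_z(z) = p_g(e^z) * e^z
    g = np.exp(z)
    return np.sum(
        0.5 * np.log(r2 / 2.0)
        - gammaln(0.5)
        - 0.5 * z
        - r2 / (2.0 * g),
        axis=-1,
    )


def _posterior_mode(design: _Design, names: list[str], r2: np.ndarray):
    """Mode and curvature of log[prior * conditional marginal] in log-g."""

    def neg_h(z):
        return -(
            _log_prior_z(z, r2)
            + _conditional_logm(design, names, np.exp(z)[None, :])[0]
        )

    z0 = np.log(r2)
    res = optimize.minimize(neg_h, z0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9,
                                     "maxiter": 4000})
    z_hat = res.x
    # central-difference Hessian
    d = len(z_hat)
    h = 1e-3
    hess = np.zeros((d, d))
    f0 = neg_h(z_hat)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            if i == j:
                hess[i, i] = (neg_h(z_hat + ei) - 2 * f0 + neg_h(z_hat - ei)) / h**2
            else:
                val = (
                    neg_h(z_hat + ei + ej)
                    - neg_h(z_hat + ei - ej)
                    - neg_h(z_hat - ei + ej)
                    + neg_h(z_hat - ei - ej)
                ) / (4 * h**2)
                hess[i, j] = hess[j, i] = val
    try:
        cov = np.linalg.inv(hess)
        # guard against non-positive curvature
        eigval, eigvec = np.linalg.eigh(cov)
        eigval = np.clip(eigval, 1e-4, 1e4)
        cov = (eigvec * eigval) @ eigvec.T
    except np.linalg.LinAlgError:
        cov = np.eye(d)
    return z_hat, cov


def _marginal_quadrature(
    design: _Design, names: list[str], r2: np.ndarray
) -> float:
    """Deterministic tensor-grid quadrature over log g (<= 2 dimensions)."""
    z_hat, cov = _posterior_mode(design, names, r2)
    sd = np.sqrt(np.diag(cov))
    axes = [
        np.linspace(z_hat[i] - QUAD_HALF_WIDTH * max(sd[i], 0.5) - 4.0,
                    z_hat[i] + QUAD_HALF_WIDTH * max(sd[i], 0.5) + 4.0,
                    QUAD_POINTS)
        for i in range(len(names))
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    z = np.stack([m.ravel() for m in mesh], axis=1)
    log_int = _log_prior_z(z, r2) + _conditional_logm(design, names, np.exp(z))
    log_vol = sum(math.log(ax[1] - ax[0]) for ax in axes)
    return float(logsumexp(log_int) + log_vol)


def _marginal_importance(
    design: _Design,
    names: list[str],
    r2: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Importance-sampled log marginal and its relative MC error.

    Proposal: defensive mixture of the g prior (mapped to log-g) and an
    inflated Laplace normal at the joint mode.
    """
    d = len(names)
    z_hat, cov = _posterior_mode(design, names, r2)
    cov = PROPOSAL_SCALE * cov
    chol = np.linalg.cholesky(cov)

    n_prior = int(round(PRIOR_MIXTURE_WEIGHT * n_samples))
    n_lap = n_samples - n_prior
    # prior component: g = r^2 / chi2_1
    g_prior = r2[None, :] / rng.chisquare(1.0, size=(n_prior, d))
    z_prior = np.log(g_prior)
    z_lap = z_hat[None, :] + rng.standard_normal((n_lap, d)) @ chol.T
    z = np.vstack([z_prior, z_lap])

    # mixture proposal density in z
    log_q_prior = _log_prior_z(z, r2)
    diff = z - z_hat[None, :]
    sol = np.linalg.solve(chol, diff.T)
    log_q_lap = (
        -0.5 * np.sum(sol**2, axis=0)
        - 0.5 * d * math.log(2 * math.pi)
        - np.sum(np.log(np.diag(chol)))
    )
    log_q = logsumexp(
        np.stack(
            [
                math.log(PRIOR_MIXTURE_WEIGHT) + log_q_prior,
                math.log(1 - PRIOR_MIXTURE_WEIGHT) + log_q_lap,
            ]
        ),
        axis=0,
    )
    log_w = (
        _log_prior_z(z, r2)
        + _conditional_logm(design, names, np.exp(z))
        - log_q
    )
    log_z = float(logsumexp(log_w) - math.log(n_samples))
    w = np.exp(log_w - log_w.max())
    rel_err = float(w.std() / (math.sqrt(n_samples) * w.mean()))
    return log_z, rel_err


def model_log_marginal(
    table: PSETable,
    spec: BFModelSpec,
    method: str = "auto",
    n_samples: int = 100_000,
    seed=None,
) -> tuple[float, float]:
    """Log marginal likelihood of one model, integrating over the g's.

    Returns ``(log_marginal, relative_mc_error)``; the error is 0 for the
    quadrature path.  ``method`` is ``"auto"`` (quadrature when the model
    has at most two g dimensions, importance sampling otherwise),
    ``"quad"`` or ``"is"``.
    """
    design = build_design(table)
    names = _check_spec_available(design, spec)
    return _model_log_marginal(design, spec, names, method, n_samples, seed)


def _model_log_marginal(design, spec, names, method, n_samples, seed):
    r2 = np.array([spec.r_scale(f) ** 2 for f in names])
    if method == "auto":
        method = "quad" if len(names) <= 2 else "is"
    if method == "quad":
        if len(names) > 2:
            raise ValueError("quadrature supports at most 2 g dimensions")
        return _marginal_quadrature(design, names, r2), 0.0
    if method == "is":
        rng = np.random.default_rng(seed)
        return _marginal_importance(design, names, r2, n_samples, rng)
    raise ValueError(f"unknown integration method {method!r}")


@dataclass(frozen=True)
class BayesFactorResult:
    """BF10 of one targeted model comparison."""

    comparison: str
    bf10: float
    log_bf10: float
    mc_error: float  # combined relative MC error of the two marginals
    n_samples: int
    interpretation: str
    log_marginal_alt: float
    log_marginal_null: float
    converged: bool = True

    def format(self) -> str:
        bf = (
            f"{self.bf10:.2e}" if self.bf10 > 1e3 or self.bf10 < 1e-3
            else f"{self.bf10:.2f}"
        )
        flag = "" if self.converged else " [high MC error]"
        return f"BF = {bf} ({self.interpretation}){flag}"


def interpret_bf(bf10: float) -> str:
    """Evidence label per the conventional Bayes-factor bands.

    BF below 1/10 is strong and 1/10-1/3 substantial evidence for the
    null; 3-10 is substantial and above 10 strong evidence for the
    alternative; the middle band is inconclusive.
    """
    if not (bf10 > 0):
        raise ValueError("bf10 must be positive")
    if bf10 < 1.0 / 10.0:
        return "strong-null"
    if bf10 < 1.0 / 3.0:
        return "substantial-null"
    if bf10 <= 3.0:
        return "inconclusive"
    if bf10 <= 10.0:
        return "substantial-alternative"
    return "strong-alternative"


def _comparison_specs(effect: str, spec: BFModelSpec):
    if effect == "shadow":
        return replace(spec, fixed_effects=("shadow",)), replace(
            spec, fixed_effects=()
        )
    if effect == "orientation":
        return replace(spec, fixed_effects=("orientation",)), replace(
            spec, fixed_effects=()
        )
    if effect == "interaction":
        return (
            replace(spec, fixed_effects=("shadow", "orientation", "interaction")),
            replace(spec, fixed_effects=("shadow", "orientation")),
        )
    raise ValueError(f"unknown effect {effect!r}")


def compare_models(
    table: PSETable,
    alt_spec: BFModelSpec,
    null_spec: BFModelSpec,
    n_samples: int = 100_000,
    seed=None,
    method: str = "auto",
    label: str | None = None,
) -> BayesFactorResult:
    """BF10 of an arbitrary pair of models on the same table.

    Each marginal gets an independent child stream of ``seed``.  Comparing
    a model with itself returns BF10 = 1 exactly (the marginals are the
    same integral by definition, so no integration is run).
    """
    label = label or (
        f"{alt_spec.fixed_effects or ('intercept',)} vs "
        f"{null_spec.fixed_effects or ('intercept',)}"
    )
    if alt_spec == null_spec:
        return BayesFactorResult(
            comparison=label, bf10=1.0, log_bf10=0.0, mc_error=0.0,
            n_samples=0, interpretation=interpret_bf(1.0),
            log_marginal_alt=float("nan"), log_marginal_null=float("nan"),
        )
    design = build_design(table)
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    seed_alt, seed_null = ss.spawn(2)
    logm_alt, err_alt = _model_log_marginal(
        design, alt_spec, _check_spec_available(design, alt_spec),
        method, n_samples, seed_alt,
    )
    logm_null, err_null = _model_log_marginal(
        design, null_spec, _check_spec_available(design, null_spec),
        method, n_samples, seed_null,
    )
    log_bf = logm_alt - logm_null
    bf10 = math.exp(log_bf)
    mc_error = math.hypot(err_alt, err_null)
    return BayesFactorResult(
        comparison=label,
        bf10=bf10,
        log_bf10=log_bf,
        mc_error=mc_error,
        n_samples=n_samples,
        interpretation=interpret_bf(bf10),
        log_marginal_alt=logm_alt,
        log_marginal_null=logm_null,
        converged=mc_error <= MC_ERROR_THRESHOLD,
    )


def bayes_factor(
    table: PSETable,
    effect: str,
    spec: BFModelSpec | None = None,
    n_samples: int = 100_000,
    seed=None,
    method: str = "auto",
) -> BayesFactorResult:
    """Default Bayes factor BF10 for one effect of the PSE design.

    Main effects compare {effect + subject} against {subject}; the
    interaction compares the full model against {both main effects +
    subject}.
    """
    if spec is None:
        spec = BFModelSpec()
    alt_spec, null_spec = _comparison_specs(effect, spec)
    return compare_models(
        table, alt_spec, null_spec, n_samples=n_samples, seed=seed,
        method=method, label=f"{effect}: alternative vs null",
    )
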