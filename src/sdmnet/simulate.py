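"""Synthetic study generator with known ground truth.

The original clinical data (29 physicians, ~10 SDM-Q-9 patient ratings each,
~3 audio-recorded consultations scored by 2 raters) are not deposited, so
this module generates rating tables with the same statistical structure and a
fully known ground truth, which every downstream estimator can be tested
against.

Generative model for patient ratings.  The analysis estimates, for every
item k, the cross-sectional multivariable regression of item k on the other
eight items.  For the ground-truth network to be recoverable at all, the
declared edge weights must *be* those conditional-regression coefficients of
some joint distribution — and the conditional regressions of a joint
Gaussian are constrained: Gamma[j, k] / d_k = Gamma[k, j] / d_j, where d_k is
the conditional (residual) variance of item k.  An arbitrary asymmetric
matrix violates this, so the generator is parameterized the only coherent
way: by a symmetric association matrix S_p (eigenvalues < 1) and per-skill
conditional variances d.  The physician's directed edge matrix is then

    Gamma_p[j, k] = S_p[j, k] * sqrt(d_k / d_j)

(asymmetry comes from skills differing in predictability), the joint
precision is D^{-1/2} (I - S_p) D^{-1/2}, and the node-wise regression of
item k on the rest has coefficients exactly Gamma_p[., k] with residual
variance d_k.  Latent item means solve mu_p = (I - Gamma_p') mu_p + alpha_p,
i.e. mu_p = (I - Gamma_p')^{-1} alpha_p, with structural intercepts alpha_p.
Latent scores are discretized by rounding half away from zero and clipping
to the Likert range.

Physician heterogeneity: alpha_p ~ N(intercept_means, random_sd_intercept^2)
and each symmetric association entry ~ N(population value, random_sd_slope^2)
— so a given directed edge varies across physicians with standard deviation
random_sd_slope * sqrt(d_k / d_j) — with draws rejected until the spectral
radius of S_p (equivalently of Gamma_p, as the two are similar matrices) is
below one (stability / positive-definiteness).

Observer ratings follow a crossed/nested random-effects model: each item
score is the instrument-scale location of the physician's true competence
plus physician, consultation-within-physician, rater (shared pool) and
residual Gaussian effects, discretized to the instrument's item range.

True competence is a documented linear combination of the physician's true
node parameters, loading on the "eliciting preferences" skill (skill 6),
whose network role drives competence in this framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observer import DEFAULT_INSTRUMENTS, InstrumentSpec

__all__ = [
    "PopulationNetworkSpec",
    "StudyDesign",
    "PhysicianTruth",
    "ObserverNoiseSpec",
    "CompetenceWeights",
    "default_network_spec",
    "default_noise_specs",
    "draw_physician_parameters",
    "simulate_patient_ratings",
    "simulate_observer_ratings",
    "true_node_parameters",
    "simulate_study",
]

N_SKILLS = 9


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3)."""
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


@dataclass(frozen=True)
class PopulationNetworkSpec:
    """Population-level generative parameters of the skills network.

    ``fixed_edges`` is the directed population edge matrix Gamma (entry
    [j, k] = edge j -> k); together with the per-skill conditional standard
    deviations ``residual_sd`` it must be *realizable* as the node-wise
    conditional regressions of a joint Gaussian, i.e. the implied
    association matrix S[j, k] = Gamma[j, k] * sqrt(d_j / d_k) must be
    symmetric with eigenvalues below one.  Build specs from a symmetric
    association matrix via :meth:`from_association` rather than assembling
    Gamma by hand.
    """

    fixed_edges: np.ndarray  # (9, 9), entry [j, k] = edge j -> k, zero diagonal
    intercept_means: np.ndarray  # (9,), structural intercepts on the item scale
    random_sd_intercept: float = 0.4
    random_sd_slope: float = 0.07
    residual_sd: np.ndarray | float = 0.9  # per-skill conditional SDs
    likert_min: int = 0
    likert_max: int = 5
    n_skills: int = N_SKILLS

    def __post_init__(self) -> None:
        B = np.asarray(self.fixed_edges, dtype=float)
        if B.shape != (self.n_skills, self.n_skills):
            raise ValueError(f"fixed_edges must be {self.n_skills}x{self.n_skills}")
        if np.any(np.diag(B) != 0):
            raise ValueError("diagonal of fixed_edges must be exactly 0")
        if np.max(np.abs(np.linalg.eigvals(B))) >= 1:
            raise ValueError("population fixed_edges must have spectral radius < 1")
        if self.likert_min >= self.likert_max:
            raise ValueError("likert_min must be < likert_max")
        if self.random_sd_intercept < 0 or self.random_sd_slope < 0:
            raise ValueError("random-effect SDs must be nonnegative")
        sd = np.broadcast_to(np.asarray(self.residual_sd, dtype=float), (self.n_skills,)).copy()
        if np.any(sd <= 0):
            raise ValueError("residual_sd must be positive")
        object.__setattr__(self, "fixed_edges", B)
        object.__setattr__(self, "residual_sd", sd)
        object.__setattr__(
            self, "intercept_means", np.asarray(self.intercept_means, dtype=float)
        )
        _association_from_edges(B, sd)  # raises if not realizable

    @classmethod
    def from_association(
        cls,
        association: np.ndarray,
        residual_sd: np.ndarray | float,
        target_means: np.ndarray,
        **kwargs,
    ) -> "PopulationNetworkSpec":
        """Construct a spec from a symmetric association matrix, per-skill
        conditional SDs, and the desired latent item means (the structural
        intercepts are solved from the means)."""
        S = np.asarray(association, dtype=float)
        if not np.allclose(S, S.T):
            raise ValueError("association matrix must be symmetric")
        sd = np.broadcast_to(np.asarray(residual_sd, dtype=float), (S.shape[0],))
        gamma = _edges_from_association(S, sd)
        alpha = (np.eye(S.shape[0]) - gamma.T) @ np.asarray(target_means, dtype=float)
        return cls(fixed_edges=gamma, intercept_means=alpha, residual_sd=sd, **kwargs)

    def reduced_form_means(self) -> np.ndarray:
        """Population expected latent item means (I - Gamma')^{-1} alpha."""
        return np.linalg.solve(np.eye(self.n_skills) - self.fixed_edges.T, self.intercept_means)

    def association(self) -> np.ndarray:
        return _association_from_edges(self.fixed_edges, self.residual_sd)


def _association_from_edges(gamma: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Invert Gamma[j,k] = S[j,k] sqrt(d_k/d_j); error if Gamma is not a
    valid conditional-regression matrix for these residual SDs."""
    S = gamma * (sd[:, None] / sd[None, :])
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError(
            "fixed_edges are not realizable as cross-sectional conditional "
            "regressions: Gamma[j,k]*d_j must equal Gamma[k,j]*d_k "
            "(build the spec via from_association)"
        )
    return (S + S.T) / 2.0


def _edges_from_association(S: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return S * (sd[None, :] / sd[:, None])


def _default_association() -> tuple[np.ndarray, np.ndarray]:
    """Symmetric association matrix and conditional SDs echoing the
    average-network structure found in the study: a dense core around
    eliciting preferences (skill 6) with presenting/informing on options
    (3, 4), deliberating (7) and selecting an option (8); a strong tie
    between focusing (1) and sharing the decision (2); supporting
    comprehension (5) and planning actions (9) attached more weakly.
    Conditional SDs differ by skill, which is what makes the directed edge
    matrix asymmetric: sharing (2) and deliberating (7) get small residual
    SDs (high outstrength), focusing (1) and eliciting preferences (6) get
    large ones (high instrength)."""
    pairs = {
        (1, 2): 0.30, (1, 3): 0.10,
        (2, 3): 0.10, (2, 7): 0.12,
        (3, 4): 0.20, (3, 6): 0.20,
        (4, 5): 0.15, (4, 6): 0.20, (4, 7): 0.15,
        (5, 6): 0.10,
        (6, 7): 0.25, (6, 8): 0.20,
        (7, 8): 0.15, (7, 9): 0.10,
        (8, 9): 0.20,
    }
    S = np.zeros((N_SKILLS, N_SKILLS))
    for (j, k), w in pairs.items():
        S[j - 1, k - 1] = S[k - 1, j - 1] = w
    sd = np.array([1.05, 0.80, 0.95, 0.95, 1.00, 1.10, 0.90, 0.95, 1.00])
    return S, sd


def default_network_spec() -> PopulationNetworkSpec:
    """Default population spec, calibrated so latent item means sit in the
    typical SDM-Q-9 range (skills 5 and 9 most activated)."""
    S, sd = _default_association()
    target_means = np.array([3.0, 3.1, 3.3, 3.2, 3.6, 3.1, 3.0, 3.3, 3.5])
    return PopulationNetworkSpec.from_association(S, sd, target_means)


@dataclass(frozen=True)
class StudyDesign:
    """Study sizes, mirroring the original design at its defaults."""

    n_physicians: int = 29
    patients_per_physician: int = 10
    recorded_consultations_per_physician: int = 3
    raters_per_consultation: int = 2
    rater_pool_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_physicians",
            "patients_per_physician",
            "recorded_consultations_per_physician",
            "raters_per_consultation",
            "rater_pool_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.raters_per_consultation > self.rater_pool_size:
            raise ValueError("raters_per_consultation cannot exceed rater_pool_size")


@dataclass(frozen=True)
class CompetenceWeights:
    """Linear map from a physician's true node parameters to true competence.

    competence = base + w_activation * (activation_6 - population value)
                      + w_outstrength * (outstrength_6 - population value)
                      + w_instrength * (instrength_6 - population value)

    centred at population values so the mean competence equals ``base``.
    """

    base: float
    w_activation: float = 9.0
    w_outstrength: float = 9.0
    w_instrength: float = 9.0
    skill: int = 6


#: Default competence maps per instrument; bases sit at the low-competence
#: levels observed in routine care (0-100 scale).
DEFAULT_COMPETENCE_WEIGHTS: dict[str, CompetenceWeights] = {
    "OPTION-12": CompetenceWeights(base=16.0),
    "OPTION-5": CompetenceWeights(base=12.0),
    "4HCS-InvestInTheEnd": CompetenceWeights(base=33.0),
}


@dataclass(frozen=True)
class ObserverNoiseSpec:
    """Variance components of the observer-rating model on the item scale."""

    var_physician: float = 0.0208
    var_consultation: float = 0.0554
    var_rater: float = 0.0128
    var_residual: float = 0.353

    def __post_init__(self) -> None:
        for name in ("var_physician", "var_consultation", "var_rater", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> float:
        return self.var_physician + self.var_consultation + self.var_rater + self.var_residual

    @property
    def icc(self) -> float:
        """Implied physician-level ICC when competence is constant."""
        return self.var_physician / self.total if self.total > 0 else 0.0


def default_noise_specs(
    instruments: dict[str, InstrumentSpec] | None = None
) -> dict[str, ObserverNoiseSpec]:
    """Per-instrument noise calibrated (on the 0-100 composite scale) to a
    physician ICC near 0.4 and an inter-rater reliability near 0.72 for the
    default 3-consultation x 2-rater design; the item-level residual variance
    scales with the instrument's item count so composite-level noise matches
    across instruments."""
    instruments = instruments or DEFAULT_INSTRUMENTS
    out = {}
    for name, spec in instruments.items():
        scale = (spec.item_max - spec.item_min) / 100.0  # 0-100 -> item units
        out[name] = ObserverNoiseSpec(
            var_physician=13.0 * scale**2,
            var_consultation=34.6 * scale**2,
            var_rater=8.0 * scale**2,
            var_residual=18.4 * spec.n_items * scale**2,
        )
    return out


@dataclass(frozen=True)
class PhysicianTruth:
    """Ground-truth parameters of one simulated physician."""

    physician_id: str
    intercepts: np.ndarray  # (9,) structural intercepts alpha_p
    edges: np.ndarray  # (9, 9) B_p, entry [j, k] = edge j -> k
    competence_true: dict[str, float] = field(default_factory=dict)

    def reduced_form_means(self) -> np.ndarray:
        M = np.eye(len(self.intercepts)) - self.edges.T
        return np.linalg.solve(M, self.intercepts)


def _population_node_parameters(spec: PopulationNetworkSpec) -> tuple[float, float, float]:
    """Population activation/outstrength/instrength of the competence skill."""
    s = DEFAULT_COMPETENCE_WEIGHTS["OPTION-12"].skill - 1
    act = spec.reduced_form_means()[s]
    out = spec.fixed_edges[s, :].sum()
    inn = spec.fixed_edges[:, s].sum()
    return float(act), float(out), float(inn)


def draw_physician_parameters(
    spec: PopulationNetworkSpec,
    design: StudyDesign,
    rng: np.random.Generator | None = None,
    competence_weights: dict[str, CompetenceWeights] | None = None,
    max_attempts: int = 1000,
) -> list[PhysicianTruth]:
    """Draw per-physician intercepts and edge matrices around the population
    values, rejecting unstable draws (spectral radius >= 1)."""
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    weights = competence_weights or DEFAULT_COMPETENCE_WEIGHTS
    pop_act, pop_out, pop_in = _population_node_parameters(spec)
    S_pop = spec.association()
    sd = spec.residual_sd
    iu = np.triu_indices(spec.n_skills, k=1)

    truths = []
    width = len(str(design.n_physicians))
    pop_means = spec.reduced_form_means()
    for p in range(design.n_physicians):
        # intercept heterogeneity lives on the item-mean scale, so physician
        # means stay in the Likert range whatever the association draw does
        mu = pop_means + rng.normal(0.0, spec.random_sd_intercept, spec.n_skills)
        for attempt in range(max_attempts):
            S = S_pop.copy()
            noise = rng.normal(0.0, spec.random_sd_slope, len(iu[0]))
            S[iu] += noise
            S.T[iu] += noise  # keep the association symmetric
            if np.max(np.abs(np.linalg.eigvalsh(S))) < 1.0:
                break
        else:
            raise RuntimeError(
                "rejection cap exceeded: the population spec implies an unstable "
                "joint distribution (spectral radius >= 1)"
            )
        gamma = _edges_from_association(S, sd)
        alpha = (np.eye(spec.n_skills) - gamma.T) @ mu
        truth = PhysicianTruth(
            physician_id=f"phys{p + 1:0{width}d}", intercepts=alpha, edges=gamma
        )
        competence = {}
        for instr, w in weights.items():
            s = w.skill - 1
            act = truth.reduced_form_means()[s]
            competence[instr] = (
                w.base
                + w.w_activation * (act - pop_act)
                + w.w_outstrength * (gamma[s, :].sum() - pop_out)
                + w.w_instrength * (gamma[:, s].sum() - pop_in)
            )
        truths.append(
            PhysicianTruth(
                physician_id=truth.physician_id,
                intercepts=alpha,
                edges=gamma,
                competence_true=competence,
            )
        )
    return truths


def simulate_patient_ratings(
    truths: list[PhysicianTruth],
    spec: PopulationNetworkSpec,
    design: StudyDesign,
    rng: np.random.Generator | None = None,
    discretize: bool = True,
) -> pd.DataFrame:
    """Long-format SDM-Q-9 table: one row per consultation with item_1..item_9.

    With ``discretize=False`` the latent (continuous) scores are returned,
    which is useful for closed-form moment checks.
    """
    if not truths:
        raise ValueError("truths must be nonempty")
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    rows = []
    eye = np.eye(spec.n_skills)
    sd = spec.residual_sd
    for truth in truths:
        M = eye - truth.edges.T
        if abs(np.linalg.det(M)) < 1e-12:
            raise ValueError(f"singular (I - Gamma') for physician {truth.physician_id}")
        mu = np.linalg.solve(M, truth.intercepts)
        S = _association_from_edges(truth.edges, sd)
        # joint covariance D^{1/2} (I - S)^{-1} D^{1/2}; Cholesky for sampling
        cov = (sd[:, None] * np.linalg.inv(eye - S)) * sd[None, :]
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"invalid truth record for physician {truth.physician_id}: "
                "implied covariance not positive definite"
            ) from exc
        z = rng.standard_normal((design.patients_per_physician, spec.n_skills))
        latent = mu[None, :] + z @ L.T
        if discretize:
            latent = np.clip(_round_half_away(latent), spec.likert_min, spec.likert_max)
        for j in range(design.patients_per_physician):
            rows.append(
                {
                    "physician_id": truth.physician_id,
                    "patient_id": f"{truth.physician_id}-pat{j + 1:02d}",
                    **{f"item_{i + 1}": latent[j, i] for i in range(spec.n_skills)},
                }
            )
    df = pd.DataFrame(rows)
    if discretize:
        for i in range(spec.n_skills):
            df[f"item_{i + 1}"] = df[f"item_{i + 1}"].astype(int)
    return df


def simulate_observer_ratings(
    truths: list[PhysicianTruth],
    noise: ObserverNoiseSpec | dict[str, ObserverNoiseSpec] | None = None,
    design: StudyDesign | None = None,
    instruments: dict[str, InstrumentSpec] | None = None,
    rng: np.random.Generator | None = None,
    discretize: bool = True,
) -> pd.DataFrame:
    """Item-level observer-rating table for the recorded consultations.

    Raters are drawn per consultation from a shared pool; rater main effects
    persist across consultations (enabling rater-variance estimation).
    """
    if not truths:
        raise ValueError("truths must be nonempty")
    design = design or StudyDesign()
    instruments = instruments or DEFAULT_INSTRUMENTS
    if noise is None:
        noise = default_noise_specs(instruments)
    if isinstance(noise, ObserverNoiseSpec):
        noise = {name: noise for name in instruments}
    rng = rng if rng is not None else np.random.default_rng(design.seed)

    rater_ids = [f"rater{r + 1}" for r in range(design.rater_pool_size)]
    max_items = max(s.n_items for s in instruments.values())
    rows = []
    # rater main effects per instrument, shared across all physicians
    rater_fx = {
        name: rng.normal(0.0, np.sqrt(noise[name].var_rater), design.rater_pool_size)
        for name in instruments
    }
    for truth in truths:
        phys_fx = {
            name: rng.normal(0.0, np.sqrt(noise[name].var_physician)) for name in instruments
        }
        for c in range(design.recorded_consultations_per_physician):
            cons_id = f"{truth.physician_id}-cons{c + 1}"
            cons_fx = {
                name: rng.normal(0.0, np.sqrt(noise[name].var_consultation))
                for name in instruments
            }
            chosen = rng.choice(
                design.rater_pool_size, size=design.raters_per_consultation, replace=False
            )
            for r in chosen:
                for name, ispec in instruments.items():
                    nspec = noise[name]
                    competence = truth.competence_true.get(name, 0.0)
                    location = ispec.item_min + competence / 100.0 * (
                        ispec.item_max - ispec.item_min
                    )
                    scores = (
                        location
                        + phys_fx[name]
                        + cons_fx[name]
                        + rater_fx[name][r]
                        + rng.normal(0.0, np.sqrt(nspec.var_residual), ispec.n_items)
                    )
                    if discretize:
                        scores = np.clip(
                            _round_half_away(scores), ispec.item_min, ispec.item_max
                        )
                    row = {
                        "physician_id": truth.physician_id,
                        "consultation_id": cons_id,
                        "rater_id": rater_ids[r],
                        "instrument": name,
                    }
                    for i in range(max_items):
                        row[f"item_{i + 1}"] = scores[i] if i < ispec.n_items else np.nan
                    rows.append(row)
    return pd.DataFrame(rows)


def true_node_parameters(truths: list[PhysicianTruth]) -> pd.DataFrame:
    """Ground-truth node parameters: activation is the reduced-form mean,
    out/instrength are row/column sums of the true edge matrix (every nonzero
    edge counts as retained, since truth carries no estimation uncertainty)."""
    if not truths:
        raise ValueError("truths must be nonempty")
    rows = []
    for truth in truths:
        act = truth.reduced_form_means()
        out = truth.edges.sum(axis=1)
        inn = truth.edges.sum(axis=0)
        for s in range(len(act)):
            rows.append(
                {
                    "physician_id": truth.physician_id,
                    "skill": s + 1,
                    "activation": act[s],
                    "outstrength": out[s],
                    "instrength": inn[s],
                }
            )
    return pd.DataFrame(rows)


def simulate_study(
    spec: PopulationNetworkSpec | None = None,
    design: StudyDesign | None = None,
    noise: ObserverNoiseSpec | dict[str, ObserverNoiseSpec] | None = None,
    instruments: dict[str, InstrumentSpec] | None = None,
    seed: int | None = None,
) -> dict:
    """Generate a complete synthetic study from one root seed.

    The root seed is split deterministically into independent streams for
    (1) physician parameters, (2) patient ratings, (3) observer ratings, so
    e.g. regenerating observer data never perturbs the patient ratings.
    """
    spec = spec or default_network_spec()
    design = design or StudyDesign()
    root = np.random.SeedSequence(design.seed if seed is None else seed)
    rng_params, rng_patient, rng_observer = (np.random.default_rng(s) for s in root.spawn(3))
    truths = draw_physician_parameters(spec, design, rng=rng_params)
    patient = simulate_patient_ratings(truths, spec, design, rng=rng_patient)
    observer = simulate_observer_ratings(
        truths, noise=noise, design=design, instruments=instruments, rng=rng_observer
    )
    return {
        "truths": truths,
        "patient_ratings": patient,
        "observer_ratings": observer,
        "true_node_parameters": true_node_parameters(truths),
        "spec": spec,
        "design": design,
    }
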