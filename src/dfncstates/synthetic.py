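"""Synthetic cohorts of state-switching component timecourses.

The generator emulates the statistical structure the dFNC analysis assumes:
each subject's brain wanders between a small number of recurring connectivity
"states"; within a state the C component timecourses are a zero-mean Gaussian
process with a state-specific correlation matrix built from network blocks
(strong within-network coupling for an intra-network state, strong
between-network coupling for inter-network states).  State switching follows a
per-subject Markov chain, so the fraction of time spent in each state — the
occupancy rate (OCR) — varies across subjects.  Symptom scores at five
follow-up timepoints are linearly coupled to the planted OCRs on top of
demographic covariate effects, with timepoint-dependent missingness.

Ground truth (state sequences, true OCRs, planted coefficients) is returned
alongside the data so recovery of states, occupancies and regression effects
can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .timecourses import ComponentTimecourses

#: The seven canonical functional networks: subcortical, auditory,
#: sensorimotor, visual, cognitive-control, default-mode, cerebellar.
DEFAULT_NETWORKS: tuple[str, ...] = ("SCN", "ADN", "SMN", "VSN", "CCN", "DMN", "CBN")

#: Symptom-score follow-up timepoints, in temporal order.
TIMEPOINTS: tuple[str, ...] = ("WK2", "WK8", "M3", "M6", "M12")

#: Phenotype-table column name for each timepoint's symptom score.
PCL5_COLUMNS: dict[str, str] = {tp: f"pcl5_{tp.lower()}" for tp in TIMEPOINTS}


# ---------------------------------------------------------------------------
# network partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of C components to named functional networks."""

    labels: tuple[str, ...]
    assignment: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("at least one network label required")
        missing = set(self.assignment) - set(self.labels)
        if missing:
            raise ValueError(f"assignment uses unknown networks: {sorted(missing)}")
        for lab in self.labels:
            if lab not in self.assignment:
                raise ValueError(f"network {lab!r} has no components")

    @property
    def n_components(self) -> int:
        return len(self.assignment)

    @property
    def n_networks(self) -> int:
        return len(self.labels)

    def indices(self, network: str) -> np.ndarray:
        """Component indices belonging to one network."""
        return np.array([i for i, a in enumerate(self.assignment) if a == network])

    def network_index(self) -> np.ndarray:
        """Per-component index into ``labels``."""
        pos = {lab: i for i, lab in enumerate(self.labels)}
        return np.array([pos[a] for a in self.assignment])


def gen_network_partition(
    n_components: int = 53,
    n_networks: int = 7,
    seed: int | None = None,
    labels: Sequence[str] | None = None,
) -> NetworkPartition:
    """Partition components into networks with balanced-as-possible block sizes.

    Components are assigned contiguously; when ``n_components`` is not a
    multiple of ``n_networks`` the seed decides which networks receive the
    extra component.
    """
    if n_components < n_networks or n_networks < 1:
        raise ValueError("need n_components >= n_networks >= 1")
    if labels is None:
        if n_networks <= len(DEFAULT_NETWORKS):
            labels = DEFAULT_NETWORKS[:n_networks]
        else:
            labels = tuple(f"NET{i + 1}" for i in range(n_networks))
    labels = tuple(labels)
    if len(labels) != n_networks:
        raise ValueError("labels length must equal n_networks")

    base, extra = divmod(n_components, n_networks)
    sizes = np.full(n_networks, base, dtype=int)
    rng = np.random.default_rng(seed)
    sizes[rng.permutation(n_networks)[:extra]] += 1
    assignment: list[str] = []
    for lab, size in zip(labels, sizes):
        assignment.extend([lab] * int(size))
    return NetworkPartition(labels=labels, assignment=tuple(assignment))


# ---------------------------------------------------------------------------
# state archetypes -> covariance matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateArchetype:
    """Blueprint for one state's C x C correlation structure.

    ``intra_block_strength`` sets the off-diagonal correlation within each
    network block (a scalar, or a per-network mapping).
    ``inter_block_strength`` sets correlations between network blocks (a
    scalar for all pairs, or an (n_networks x n_networks) symmetric matrix,
    or a mapping from frozenset/tuple of network names to a value).
    ``noise_sd`` is the standard deviation of white observation noise added
    to the latent signal; it attenuates all off-diagonal correlations by
    1/(1 + noise_sd**2) while keeping unit variances.
    """

    name: str
    intra_block_strength: float | Mapping[str, float] = 0.5
    inter_block_strength: float | np.ndarray | Mapping = 0.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if not self.noise_sd >= 0:
            raise ValueError("noise_sd must be nonnegative")


def _intra_value(arch: StateArchetype, network: str) -> float:
    v = arch.intra_block_strength
    return float(v.get(network, 0.0)) if isinstance(v, Mapping) else float(v)


def _inter_value(arch: StateArchetype, partition: NetworkPartition, a: int, b: int) -> float:
    v = arch.inter_block_strength
    if isinstance(v, Mapping):
        la, lb = partition.labels[a], partition.labels[b]
        for key in ((la, lb), (lb, la), frozenset((la, lb))):
            if key in v:
                return float(v[key])
        return 0.0
    arr = np.asarray(v, dtype=float)
    if arr.ndim == 0:
        return float(arr)
    return float(arr[a, b])


def state_correlation(partition: NetworkPartition, archetype: StateArchetype) -> np.ndarray:
    """Build the archetype's latent C x C correlation matrix (before noise).

    Strengths must lie in (-1, 1).  If the block construction is not positive
    definite it is repaired by shrinkage toward the identity, keeping the unit
    diagonal.
    """
    net_idx = partition.network_index()
    C = partition.n_components
    R = np.empty((C, C))
    for a in range(partition.n_networks):
        ia = net_idx == a
        R[np.ix_(ia, ia)] = _intra_value(archetype, partition.labels[a])
        for b in range(a + 1, partition.n_networks):
            ib = net_idx == b
            val = _inter_value(archetype, partition, a, b)
            R[np.ix_(ia, ib)] = val
            R[np.ix_(ib, ia)] = val
    off = R[~np.eye(C, dtype=bool)]
    if off.size and (np.abs(off) >= 1).any():
        raise ValueError("block strengths must lie in (-1, 1)")
    np.fill_diagonal(R, 1.0)

    eps = 1e-6
    w = np.linalg.eigvalsh(R)
    if w[0] <= eps:
        # convex shrinkage (1-a)R + aI keeps the unit diagonal and lifts the
        # smallest eigenvalue to eps
        a = (eps - w[0]) / (1.0 - w[0])
        R = (1.0 - a) * R + a * np.eye(C)
        if np.linalg.eigvalsh(R)[0] <= 0:
            raise RuntimeError(f"state {archetype.name!r}: repair failed")
    return R


def gen_state_covariances(
    partition: NetworkPartition, archetypes: Sequence[StateArchetype]
) -> list[np.ndarray]:
    """Emission covariance per state: noise-attenuated block correlations.

    Each returned matrix is ``(R + noise_sd**2 I) / (1 + noise_sd**2)`` —
    symmetric positive definite with a unit diagonal, so it is simultaneously
    the covariance and the correlation of the emitted signal.
    """
    if not archetypes:
        raise ValueError("need at least one archetype")
    covs = []
    for arch in archetypes:
        R = state_correlation(partition, arch)
        s2 = arch.noise_sd**2
        covs.append((R + s2 * np.eye(partition.n_components)) / (1.0 + s2))
    return covs


def default_archetypes(noise_sd: float = 0.1) -> list[StateArchetype]:
    """Three-state design: one intra-network state and two inter-network states.

    State 1 couples components only within their own network; states 2 and 3
    add strong positive coupling among the sensory networks (auditory,
    sensorimotor, visual), with state 3 additionally linking the default-mode
    network to the sensory networks and the cerebellar to the subcortical
    network.
    """
    sensory = [("ADN", "SMN"), ("ADN", "VSN"), ("SMN", "VSN")]
    inter2: dict = {frozenset(p): 0.45 for p in sensory}
    inter3: dict = {frozenset(p): 0.55 for p in sensory}
    for net in ("ADN", "SMN", "VSN"):
        inter3[frozenset((net, "DMN"))] = 0.35
    inter3[frozenset(("CBN", "SCN"))] = 0.4
    return [
        StateArchetype("intra", intra_block_strength=0.65, inter_block_strength=0.0,
                       noise_sd=noise_sd),
        StateArchetype("inter-sensory", intra_block_strength=0.3,
                       inter_block_strength=inter2, noise_sd=noise_sd),
        StateArchetype("inter-global",
                       intra_block_strength={"SCN": 0.3, "ADN": 0.35, "SMN": 0.35,
                                             "VSN": 0.35, "CCN": 0.5, "DMN": 0.3,
                                             "CBN": 0.5},
                       inter_block_strength=inter3, noise_sd=noise_sd),
    ]


# ---------------------------------------------------------------------------
# Markov state dynamics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkovDesign:
    """Group-level Markov chain over K states, with per-subject perturbation.

    Each subject's transition matrix is drawn row-wise from a Dirichlet
    centred on the group matrix with concentration ``subject_concentration``;
    larger values mean subjects stay closer to the group dynamics (and have
    less occupancy variance).
    """

    K: int = 3
    transition: np.ndarray | None = None
    initial: np.ndarray | None = None
    subject_concentration: float = 200.0

    def __post_init__(self) -> None:
        K = self.K
        if K < 1:
            raise ValueError("K must be >= 1")
        T = self.transition
        if T is None:
            # mean dwell time 50 samples by default
            T = np.full((K, K), 0.02 / max(K - 1, 1))
            np.fill_diagonal(T, 0.98 if K > 1 else 1.0)
        T = np.asarray(T, dtype=float)
        if T.shape != (K, K) or (T < 0).any() or not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition must be a K x K row-stochastic matrix")
        init = self.initial
        if init is None:
            init = self.stationary_of(T)
        init = np.asarray(init, dtype=float)
        if init.shape != (K,) or (init < 0).any() or not np.isclose(init.sum(), 1.0, atol=1e-12):
            raise ValueError("initial must be a probability K-vector")
        if not self.subject_concentration > 0:
            raise ValueError("subject_concentration must be positive")
        object.__setattr__(self, "transition", T)
        object.__setattr__(self, "initial", init)

    @staticmethod
    def stationary_of(transition: np.ndarray) -> np.ndarray:
        """Stationary distribution via the leading left eigenvector."""
        w, v = np.linalg.eig(np.asarray(transition, dtype=float).T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def stationary(self) -> np.ndarray:
        return self.stationary_of(self.transition)

    def subject_transition(self, rng: np.random.Generator) -> np.ndarray:
        """One subject's Dirichlet-perturbed transition matrix."""
        out = np.zeros_like(self.transition)
        for i, row in enumerate(self.transition):
            pos = row > 0
            out[i, pos] = rng.dirichlet(self.subject_concentration * row[pos])
        return out


def gen_state_sequence(
    T: int,
    design: MarkovDesign,
    seed: int | np.random.Generator | None = None,
    transition: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a length-T state sequence (1-based labels in 1..K)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    P = design.transition if transition is None else np.asarray(transition, dtype=float)
    if P.shape != (design.K, design.K) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition must be K x K row-stochastic")
    seq = np.empty(T, dtype=int)
    # inverse-CDF sampling from one uniform stream keeps the draw reproducible
    u = rng.random(T)
    cum0 = np.cumsum(design.initial)
    seq[0] = np.searchsorted(cum0, u[0], side="right")
    cums = np.cumsum(P, axis=1)
    for t in range(1, T):
        seq[t] = np.searchsorted(cums[seq[t - 1]], u[t], side="right")
    return seq + 1


def gen_timecourses(
    state_sequence: np.ndarray,
    covariances: Sequence[np.ndarray],
    seed: int | np.random.Generator | None = None,
    tr: float = 2.36,
    subject_id: str = "sub-0001",
) -> ComponentTimecourses:
    """Emit row t from a zero-mean multivariate normal with the covariance of
    the state active at t."""
    seq = np.asarray(state_sequence, dtype=int)
    if seq.min() < 1 or seq.max() > len(covariances):
        raise ValueError("state sequence refers to states without a covariance")
    C = covariances[0].shape[0]
    for cov in covariances:
        if cov.shape != (C, C):
            raise ValueError("all covariances must share the same dimension")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    z = rng.standard_normal((len(seq), C))
    out = np.empty_like(z)
    for k, cov in enumerate(covariances, start=1):
        mask = seq == k
        if mask.any():
            L = np.linalg.cholesky(cov)
            out[mask] = z[mask] @ L.T
    return ComponentTimecourses(subject_id=subject_id, data=out, tr=tr)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortDesign:
    """Study-level design for a synthetic cohort.

    ``effect`` gives the linear coefficients (symptom points per unit
    occupancy proportion) of each state's OCR on the outcome, applied at the
    timepoints in ``effect_timepoints``.  Missingness is completely at random
    per timepoint; the default rates reproduce the observed per-timepoint
    sample attrition (275, 243, 226, 208, 176 of 275).
    """

    n_subjects: int = 275
    T: int = 210
    tr: float = 2.36  # inferred from a 20-sample window spanning 47.2 s
    effect: np.ndarray | Sequence[float] | None = None
    effect_timepoints: tuple[str, ...] = TIMEPOINTS
    outcome_noise_sd: float = 16.0
    intercepts: Mapping[str, float] = field(
        default_factory=lambda: {"WK2": 30.1, "WK8": 26.6, "M3": 23.5, "M6": 21.0, "M12": 20.3}
    )
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {"WK2": 0.0, "WK8": 0.116, "M3": 0.178, "M6": 0.244, "M12": 0.36}
    )
    p_female: float = 0.66
    n_sites: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.T < 2:
            raise ValueError("T too small")
        for tp, p in self.missingness.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missingness[{tp}] outside [0, 1]")


# modest covariate effects on the outcome (symptom points per unit)
_COVARIATE_EFFECTS = {
    "age": 0.05,          # per year, centred at 35
    "sex_female": 2.0,
    "education": -0.5,    # per year, centred at 15
    "income_level": -0.8,  # per ordered level, centred at 3
    "adi_percentile": 0.03,  # per percentile, centred at 50
}
_SITE_EFFECTS = (0.0, 1.0, -1.0, 0.5, -0.5)
_MARITAL_LEVELS = ("single", "married", "other")
_MARITAL_PROBS = (0.5, 0.35, 0.15)
_MARITAL_EFFECTS = (0.0, -1.0, 1.0)
_EMPLOY_LEVELS = ("employed", "unemployed", "other")
_EMPLOY_PROBS = (0.6, 0.3, 0.1)
_EMPLOY_EFFECTS = (0.0, 2.0, 0.5)
_INCOME_PROBS = (0.278, 0.320, 0.150, 0.113, 0.064, 0.075)


@dataclass
class Cohort:
    """A generated cohort: data, phenotypes and the planted ground truth."""

    timecourses: list[ComponentTimecourses] | None
    phenotypes: pd.DataFrame
    truth: dict

    @property
    def subject_ids(self) -> list[str]:
        return list(self.phenotypes["subject_id"])

    def truth_ocr_table(self) -> pd.DataFrame:
        ocr = self.truth["ocr"]
        cols = [f"state_{k + 1}" for k in range(ocr.shape[1])]
        return pd.DataFrame(ocr, index=pd.Index(self.subject_ids, name="subject_id"),
                            columns=cols)


def _draw_covariates(n: int, design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    age = stats.truncnorm.rvs((18 - 35) / 13, (65 - 35) / 13, loc=35, scale=13,
                              size=n, random_state=rng)
    sex = np.where(rng.random(n) < design.p_female, "female", "male")
    education = np.clip(rng.normal(15.2, 2.3, size=n), 8, 22)
    income = 1 + rng.choice(len(_INCOME_PROBS), size=n,
                            p=np.asarray(_INCOME_PROBS) / sum(_INCOME_PROBS))
    marital = rng.choice(_MARITAL_LEVELS, size=n, p=_MARITAL_PROBS)
    employment = rng.choice(_EMPLOY_LEVELS, size=n, p=_EMPLOY_PROBS)
    site = rng.choice([f"site{i + 1}" for i in range(design.n_sites)], size=n)
    adi = rng.uniform(0, 100, size=n)
    return pd.DataFrame({
        "age": np.round(age, 1),
        "sex": sex,
        "education": np.round(education, 1),
        "income_level": income,
        "marital": marital,
        "employment": employment,
        "site": site,
        "adi_percentile": np.round(adi, 1),
    })


def _covariate_contribution(cov: pd.DataFrame) -> np.ndarray:
    eff = _COVARIATE_EFFECTS
    out = (
        eff["age"] * (cov["age"].to_numpy() - 35.0)
        + eff["sex_female"] * (cov["sex"].to_numpy() == "female")
        + eff["education"] * (cov["education"].to_numpy() - 15.0)
        + eff["income_level"] * (cov["income_level"].to_numpy() - 3.0)
        + eff["adi_percentile"] * (cov["adi_percentile"].to_numpy() - 50.0)
    )
    site_i = cov["site"].str.removeprefix("site").astype(int).to_numpy() - 1
    out = out + np.asarray(_SITE_EFFECTS)[site_i]
    out = out + np.asarray(_MARITAL_EFFECTS)[
        [list(_MARITAL_LEVELS).index(m) for m in cov["marital"]]]
    out = out + np.asarray(_EMPLOY_EFFECTS)[
        [list(_EMPLOY_LEVELS).index(e) for e in cov["employment"]]]
    return out


def gen_cohort(
    design: CohortDesign,
    partition: NetworkPartition | None = None,
    archetypes: Sequence[StateArchetype] | None = None,
    markov: MarkovDesign | None = None,
    seed: int | None = None,
    include_timecourses: bool = True,
) -> Cohort:
    """Generate a full synthetic cohort.

    Returns timecourses (unless ``include_timecourses`` is False, which keeps
    only state sequences and occupancies — useful for statistical experiments
    that do not need the imaging layer), a phenotype table, and ground truth.
    """
    if partition is None:
        partition = gen_network_partition(seed=0)
    if archetypes is None:
        archetypes = default_archetypes()
    if markov is None:
        markov = MarkovDesign(K=len(archetypes))
    if markov.K != len(archetypes):
        raise ValueError("number of archetypes must equal markov.K")

    seed = design.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    ss_pheno, ss_subjects = root.spawn(2)
    rng_pheno = np.random.default_rng(ss_pheno)
    subject_streams = ss_subjects.spawn(design.n_subjects)

    covariances = gen_state_covariances(partition, archetypes)
    n = design.n_subjects
    width = max(4, len(str(n)))
    subject_ids = [f"sub-{i + 1:0{width}d}" for i in range(n)]

    sequences: list[np.ndarray] = []
    transitions: list[np.ndarray] = []
    tcs: list[ComponentTimecourses] | None = [] if include_timecourses else None
    ocr = np.zeros((n, markov.K))
    for i, sid in enumerate(subject_ids):
        rng_i = np.random.default_rng(subject_streams[i])
        P_i = markov.subject_transition(rng_i)
        seq = gen_state_sequence(design.T, markov, seed=rng_i, transition=P_i)
        sequences.append(seq)
        transitions.append(P_i)
        ocr[i] = np.bincount(seq, minlength=markov.K + 1)[1:] / design.T
        if tcs is not None:
            tcs.append(gen_timecourses(seq, covariances, seed=rng_i, tr=design.tr,
                                       subject_id=sid))

    pheno = _draw_covariates(n, design, rng_pheno)
    pheno.insert(0, "subject_id", subject_ids)

    effect = np.zeros(markov.K) if design.effect is None else np.asarray(design.effect, float)
    if effect.shape != (markov.K,):
        raise ValueError("effect must be a length-K vector")
    cov_part = _covariate_contribution(pheno)
    for tp in TIMEPOINTS:
        y = design.intercepts.get(tp, 25.0) + cov_part.copy()
        if tp in design.effect_timepoints:
            y = y + ocr @ effect
        y = y + rng_pheno.normal(0.0, design.outcome_noise_sd, size=n)
        y = np.clip(np.round(y), 0, 80)
        miss = rng_pheno.random(n) < design.missingness.get(tp, 0.0)
        y = y.astype(float)
        y[miss] = np.nan
        pheno[PCL5_COLUMNS[tp]] = y

    truth = {
        "subject_ids": subject_ids,
        "state_sequences": sequences,
        "ocr": ocr,
        "transition_matrices": transitions,
        "effect": effect,
        "effect_timepoints": tuple(design.effect_timepoints),
    }
    return Cohort(timecourses=tcs, phenotypes=pheno, truth=truth)


# ---------------------------------------------------------------------------
# effect-size calibration
# ---------------------------------------------------------------------------


def effect_for_target_r(target_r: float, ocr_sd: float, noise_sd: float) -> float:
    """Coefficient planting a partial correlation of ``target_r`` between an
    OCR column with standard deviation ``ocr_sd`` and an outcome with residual
    noise ``noise_sd``."""
    if not -1 < target_r < 1:
        raise ValueError("target_r must lie in (-1, 1)")
    if ocr_sd <= 0 or noise_sd <= 0:
        raise ValueError("standard deviations must be positive")
    return target_r / np.sqrt(1 - target_r**2) * noise_sd / ocr_sd


def simulated_ocr_sd(
    markov: MarkovDesign, T: int, state: int = 1, n_subjects: int = 2000,
    seed: int = 12345,
) -> float:
    """Monte-Carlo standard deviation of one state's true OCR under a design.

    Used to size planted outcome effects before generating a cohort.
    """
    root = np.random.SeedSequence(seed)
    ocrs = np.empty(n_subjects)
    for i, ss in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(ss)
        P = markov.subject_transition(rng)
        seq = gen_state_sequence(T, markov, seed=rng, transition=P)
        ocrs[i] = np.mean(seq == state)
    return float(np.std(ocrs, ddof=1))
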