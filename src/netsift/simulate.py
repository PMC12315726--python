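"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates an aging-cohort rsFC study: ages drawn uniformly on
a configurable range (44-82 years by default), binary sex, five standard-
normal imaging confounds, Gaussian edge noise around a constant Fisher-z
baseline, and one or more *planted* node subsets whose intra-subset edges
decline linearly (optionally quadratically) with age.  White-matter
mediators (mean FA, log WMH volume) are generated from age, and can be
coupled into the first planted subnetwork's edges so that an
age -> mediator -> mean-rsFC chain with a known proportion mediated holds in
expectation.  A nine-assessment cognitive battery loads on a single latent
factor correlated with the planted subnetwork's mean connectivity; with the
default loadings the battery's first principal component explains ~70% of
total variance.  Edge missingness is completely at random.

Conventions
-----------
* ``beta_age`` is the per-edge linear age effect in Fisher-z units per year,
  applied to mean-centered age, so an OLS slope on age in years recovers it.
* Mediation path coefficients act on z-scored age (``age_z``) and
  standardized latent mediators; ``outcome_scale`` converts the chain's
  output into Fisher-z edge units and cancels from the proportion mediated.
* The same ``seed`` always reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import ConnectomeStack, EdgeIndex, ParcellationInfo, SubjectTable, edge_count


class InvalidSpecError(ValueError):
    pass


@dataclass
class PlantedSubnetworkSpec:
    """A node subset whose intra-subset edges carry an age effect."""

    nodes: tuple
    beta_age: float = -0.003  # z units per year
    beta_age_sq: float = 0.0
    hub_nodes: tuple = ()

    def __post_init__(self):
        self.nodes = tuple(sorted(set(int(v) for v in self.nodes)))
        self.hub_nodes = tuple(sorted(set(int(v) for v in self.hub_nodes)))
        if len(self.nodes) < 2:
            raise InvalidSpecError("a planted subnetwork needs >= 2 nodes")
        if not set(self.hub_nodes) <= set(self.nodes):
            raise InvalidSpecError("hub_nodes must be a subset of nodes")


@dataclass
class MediationSpec:
    """Path coefficients of the age -> mediator -> rsFC chain.

    ``a_*`` are age-to-mediator paths (per SD of age), ``b_*``
    mediator-to-outcome paths, ``c_prime`` the direct age path.  The chain's
    edge-level footprint is multiplied by ``outcome_scale``; with the default
    0 the mediators are generated but not coupled into the connectome.
    """

    a_fa: float = -0.5
    b_fa: float = 0.4
    a_wmh: float = -0.5
    b_wmh: float = 0.3
    c_prime: float = -0.8
    outcome_scale: float = 0.0

    def implied_prop_mediated(self, mediator: str = "fa") -> float:
        """Closed-form proportion mediated for single-mediator analysis.

        Analyzing one mediator at a time, the other chain's age-driven part
        is absorbed into the direct path, so the denominator is the full
        total effect.
        """
        total = self.a_fa * self.b_fa + self.a_wmh * self.b_wmh + self.c_prime
        if mediator == "fa":
            return self.a_fa * self.b_fa / total
        if mediator == "wmh":
            return self.a_wmh * self.b_wmh / total
        raise ValueError("mediator must be 'fa' or 'wmh'")


@dataclass
class CohortSpec:
    n_subjects: int
    n_nodes: int
    age_range: tuple = (44.0, 82.0)
    planted: list = field(default_factory=list)
    noise_sd: float = 0.3
    baseline: float = 0.25
    confound_betas: tuple = (0.01, 0.01, 0.01, 0.01, 0.01)
    sex_beta: float = 0.01
    missing_rate: float = 0.0
    mediation: MediationSpec = field(default_factory=MediationSpec)
    cog_loadings: tuple = (1.4,) * 9
    cog_rsfc_rho: float = 0.3
    cog_noise_sd: float = 1.0
    cog_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2 or self.n_nodes < 2:
            raise InvalidSpecError("need at least 2 subjects and 2 nodes")
        if not (self.noise_sd > 0):
            raise InvalidSpecError("noise_sd must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise InvalidSpecError("missing_rate must be in [0, 1)")
        if len(self.confound_betas) != 5:
            raise InvalidSpecError("confound_betas must have 5 entries")
        if len(self.cog_loadings) != 9:
            raise InvalidSpecError("cog_loadings must have 9 entries")
        planted = []
        for p in self.planted:
            if isinstance(p, dict):
                p = PlantedSubnetworkSpec(**p)
            if p.nodes[-1] >= self.n_nodes or p.nodes[0] < 0:
                raise InvalidSpecError(
                    f"planted nodes {p.nodes} out of range 0..{self.n_nodes - 1}"
                )
            planted.append(p)
        self.planted = planted
        if isinstance(self.mediation, dict):
            self.mediation = MediationSpec(**self.mediation)


def _intra_edge_columns(nodes, n_nodes):
    idx = EdgeIndex(n_nodes)
    nodes = sorted(nodes)
    return [idx.index_of(i, j) for k, i in enumerate(nodes) for j in nodes[k + 1 :]]


def generate_cohort(spec: CohortSpec):
    """Draw one cohort: ``(ConnectomeStack, SubjectTable, ground_truth dict)``.

    The ground-truth record carries the planted node sets, their effect
    sizes, the mediation path coefficients and the implied proportions
    mediated, for recovery scoring by :func:`planted_truth`.
    """
    rng = np.random.default_rng(spec.seed)
    n, N = spec.n_subjects, spec.n_nodes
    E = edge_count(N)

    age = rng.uniform(*spec.age_range, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    confounds = rng.standard_normal((n, 5))
    age_c = age - age.mean()
    age_sd = age.std()
    age_z = age_c / age_sd if age_sd > 0 else age_c

    # latent standardized mediators driven by age
    med = spec.mediation
    e_fa = rng.standard_normal(n) * np.sqrt(max(1.0 - med.a_fa**2, 0.05))
    e_wmh = rng.standard_normal(n) * np.sqrt(max(1.0 - med.a_wmh**2, 0.05))
    m_fa = med.a_fa * age_z + e_fa
    m_wmh = med.a_wmh * age_z + e_wmh

    values = np.full((n, E), spec.baseline)
    values += spec.sex_beta * sex[:, None]
    values += (confounds @ np.asarray(spec.confound_betas))[:, None]
    for p in spec.planted:
        cols = _intra_edge_columns(p.nodes, N)
        effect = p.beta_age * age_c + p.beta_age_sq * age_c**2
        values[:, cols] += effect[:, None]
    if spec.planted and med.outcome_scale != 0.0:
        cols = _intra_edge_columns(spec.planted[0].nodes, N)
        chain = med.outcome_scale * (
            med.c_prime * age_z + med.b_fa * m_fa + med.b_wmh * m_wmh
        )
        values[:, cols] += chain[:, None]
    values += rng.normal(0.0, spec.noise_sd, size=(n, E))

    missing = np.zeros((n, E), dtype=bool)
    if spec.missing_rate > 0:
        missing = rng.random((n, E)) < spec.missing_rate

    # cognitive battery on one latent factor tied to subnetwork connectivity
    if spec.planted:
        cols = _intra_edge_columns(spec.planted[0].nodes, N)
        mean_fc = values[:, cols].mean(axis=1)
    else:
        mean_fc = values.mean(axis=1)
    fc_z = (mean_fc - mean_fc.mean()) / (mean_fc.std() or 1.0)
    rho = spec.cog_rsfc_rho
    latent = rho * fc_z + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(n)
    loadings = np.asarray(spec.cog_loadings)
    battery = latent[:, None] * loadings[None, :] + rng.normal(
        0.0, spec.cog_noise_sd, size=(n, 9)
    )
    if spec.cog_missing_rate > 0:
        battery[rng.random(battery.shape) < spec.cog_missing_rate] = np.nan

    subject_ids = [f"sub-{k:05d}" for k in range(n)]
    table = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": age,
            "sex": sex.astype(int),
            **{c: confounds[:, k] for k, c in enumerate(SubjectTable.CONFOUNDS)},
            "fa": 0.45 + 0.05 * m_fa,
            "log_wmh": 8.5 + 0.8 * m_wmh,
            **{c: battery[:, k] for k, c in enumerate(SubjectTable.COGNITIVE)},
        }
    )
    stack = ConnectomeStack(subject_ids, N, values, missing)
    truth = {
        "planted": [
            {
                "nodes": list(p.nodes),
                "beta_age": p.beta_age,
                "beta_age_sq": p.beta_age_sq,
                "hub_nodes": list(p.hub_nodes),
            }
            for p in spec.planted
        ],
        "mediation": asdict(med),
        "implied_prop_mediated_fa": med.implied_prop_mediated("fa"),
        "implied_prop_mediated_wmh": med.implied_prop_mediated("wmh"),
        "latent_cog_rho": rho,
        "age_mean": float(age.mean()),
        "age_sd": float(age_sd),
        "seed": spec.seed,
    }
    return stack, SubjectTable(table), truth


def planted_truth(ground_truth: dict):
    """Planted node sets and (a, b, c') coefficients from a ground-truth record."""
    sets = [set(p["nodes"]) for p in ground_truth["planted"]]
    m = ground_truth["mediation"]
    paths = (m["a_fa"], m["b_fa"], m["a_wmh"], m["b_wmh"], m["c_prime"])
    return sets, paths


def default_parcellation(
    n_nodes: int,
    networks=("Visual", "Somatomotor", "DorsalAttention", "VentralAttention",
              "Limbic", "Frontoparietal", "Default"),
) -> ParcellationInfo:
    """Synthetic parcellation cycling nodes through predefined network names."""
    rows = {
        "node_id": np.arange(n_nodes),
        "label": [f"region_{k:03d}" for k in range(n_nodes)],
        "lobe": [f"lobe_{k % 5}" for k in range(n_nodes)],
        "network": [networks[k % len(networks)] for k in range(n_nodes)],
    }
    return ParcellationInfo(pd.DataFrame(rows))


def simulate_mediation_dataset(
    a: float,
    b: float,
    c_prime: float,
    n: int,
    noise_mediator: float = 1.0,
    noise_outcome: float = 1.0,
    seed: int = 0,
):
    """Standalone age/mediator/outcome draw with known linear paths.

    ``age`` is standard normal (z-scored years), ``mediator = a*age + e1``,
    ``outcome = c_prime*age + b*mediator + e2``; sex enters both equations
    with a small effect so adjusted fits are exercised.  Returns
    ``(age, mediator, outcome, sex)``.
    """
    rng = np.random.default_rng(seed)
    age = rng.standard_normal(n)
    sex = rng.integers(0, 2, size=n).astype(float)
    mediator = a * age + 0.1 * sex + rng.normal(0, noise_mediator, n)
    outcome = c_prime * age + b * mediator + 0.1 * sex + rng.normal(0, noise_outcome, n)
    return age, mediator, outcome, sex
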