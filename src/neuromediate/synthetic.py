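"""Synthetic cohorts with a known PGS → brain → intelligence mediation structure.

The generator emulates the statistical skeleton of a genetic neuroimaging
study: two standard-normal polygenic scores (an educational-attainment-like
and a general-intelligence-like score) influence designated brain properties
— regional surface area, cortical thickness, or the edge weights incident to
hub nodes of the structural connectome — which in turn influence an
intelligence sum score, alongside a direct genetic effect and age/sex/ancestry
covariate effects.  Every path coefficient used is recorded in a
:class:`TrueModel` so that recovery by the analysis pipeline can be scored
against ground truth.

Calibration: with the default configuration the direct effects are solved so
that the total standardized PGS → outcome effect τ_k satisfies
τ_k² = target incremental R² (3.3% for the EA-like and 4.8% for the GI-like
score), and the outcome noise is set analytically so Var(outcome) = 1 —
hence the incremental R² over the covariates matches the target in
expectation.

Structural edge weights follow a shared lognormal template with subject-level
multiplicative noise (streamline counts are heavily right-skewed); a
configured fraction of edges is truly absent, with subject-wise values
hovering around zero, so that group pruning has spurious connections to find.
Functional data are simulated as node-level time courses from a low-rank
network factor model plus shared nuisance signals (motion-like, white-matter-
and ventricle-like), which the connectivity step regresses out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import GroupConnectivity, functional_connectivity

# rng stream ids, combined with the master seed as default_rng([seed, stream, ...])
_PHENO, _TEMPLATE, _STRUCT, _FUNC, _OUTLIER = 0, 1, 2, 3, 4

COVARIATE_NAMES = ("age", "sex", "pc1", "pc2", "pc3", "pc4")
MODALITIES = ("surface_area", "thickness", "structural_efficiency", "functional_efficiency")


@dataclass
class TrueMediator:
    """One designated mediator region with its standardized paths."""

    modality: str
    region: str
    a: float  # PGS -> mediator
    b: float  # mediator -> outcome
    pgs: str = "EA"  # which score drives path a

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.pgs not in ("EA", "GI"):
            raise ValueError("pgs must be 'EA' or 'GI'")
        if not (abs(self.a) < 1 and abs(self.b) < 1):
            raise ValueError("standardized paths must have |value| < 1")


@dataclass
class EdgeWeightModel:
    """Heavy-tailed structural weights: lognormal template x subject noise."""

    log_mean: float = 3.0
    log_sd: float = 1.0
    subject_log_sd: float = 0.3
    zero_fraction: float = 0.35  # fraction of truly absent (spurious) edges
    zero_noise_sd: float = 0.02  # subject-wise jitter of absent edges
    kappa: float = 0.15  # efficiency-mediator edge scaling per latent unit

    def __post_init__(self) -> None:
        if not 0 <= self.zero_fraction <= 1:
            raise ValueError("zero_fraction must be in [0, 1]")


@dataclass
class FunctionalModel:
    """Node time courses: network factors + shared nuisance + white noise."""

    n_timepoints: int = 208
    n_networks: int = 12
    network_loading: float = 0.55
    global_loading: float = 0.25
    n_nuisance: int = 8  # motion-like + white-matter-like + ventricle-like
    nuisance_loading_sd: float = 0.4
    noise_sd: float = 1.0
    isolated_regions: tuple[str, ...] | None = None  # default: last cortical region

    def __post_init__(self) -> None:
        if self.n_timepoints <= 0:
            raise ValueError("n_timepoints must be positive")


def default_true_mediators(
    n_cortical: int = 180, n_subcortical: int = 8
) -> list[TrueMediator]:
    """5 surface-area + 3 structural-efficiency mediators split across PGS.

    With the full parcellation the canonical regions below are used; smaller
    parcellations get the same path structure on 7 evenly spaced cortical
    regions (plus SC1 where subcortex exists).
    """
    if n_cortical >= 24:
        regions = ["A004", "A007", "A012", "A009", "A016", "A021", "A024"]
    else:
        if n_cortical < 7:
            raise ValueError("default mediator set needs at least 7 cortical regions")
        idx = np.linspace(1, n_cortical, num=7, dtype=int)
        regions = [f"A{i:03d}" for i in idx]
    sc = "SC1" if n_subcortical >= 1 else None
    meds = [
        TrueMediator("surface_area", regions[0], a=0.20, b=0.15, pgs="EA"),
        TrueMediator("surface_area", regions[1], a=0.20, b=0.15, pgs="EA"),
        TrueMediator("surface_area", regions[2], a=0.20, b=0.15, pgs="EA"),
        TrueMediator("structural_efficiency", regions[3], a=0.20, b=0.10, pgs="EA"),
        TrueMediator("surface_area", regions[4], a=0.25, b=0.20, pgs="GI"),
        TrueMediator("surface_area", regions[5], a=0.25, b=0.20, pgs="GI"),
        TrueMediator("structural_efficiency", regions[6], a=0.25, b=0.16, pgs="GI"),
    ]
    if sc is not None:
        meds.insert(4, TrueMediator("structural_efficiency", sc, a=0.20, b=0.10, pgs="EA"))
    return meds


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults are the study conditions."""

    n_subjects: int = 557
    seed: int = 0
    nodes_cortical_per_hemi: int = 180
    nodes_subcortical_per_hemi: int = 8
    true_mediators: list[TrueMediator] | None = None  # None -> defaults
    direct_effect: dict[str, float] | None = None  # None -> solved from targets
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "outcome": {"age": -0.10, "sex": 0.05},
            "mediators": {"age": -0.10},
        }
    )
    target_incremental_r2: dict[str, float] = field(
        default_factory=lambda: {"EA": 0.033, "GI": 0.048}
    )
    edge_weight_model: EdgeWeightModel = field(default_factory=EdgeWeightModel)
    functional_noise: FunctionalModel = field(default_factory=FunctionalModel)
    outlier_injection: int = 0
    include_structural: bool = True
    include_functional: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.nodes_cortical_per_hemi <= 0 or self.nodes_subcortical_per_hemi < 0:
            raise ValueError("node counts must be positive")
        if self.true_mediators is None:
            self.true_mediators = default_true_mediators(
                self.nodes_cortical_per_hemi, self.nodes_subcortical_per_hemi
            )
        for t in self.target_incremental_r2.values():
            if not 0 <= t < 1:
                raise ValueError("target incremental R² must be in [0, 1)")
        if self.outlier_injection < 0:
            raise ValueError("outlier_injection must be non-negative")
        valid = set(self.cortical_regions()) | set(self.subcortical_regions())
        for med in self.true_mediators:
            if med.region not in valid:
                raise ValueError(
                    f"mediator region {med.region!r} not in the configured parcellation"
                )
            if med.modality in ("surface_area", "thickness", "functional_efficiency") and (
                med.region not in self.cortical_regions()
            ):
                raise ValueError(f"{med.modality} mediator {med.region!r} must be cortical")

    def cortical_regions(self) -> list[str]:
        return [f"A{i + 1:03d}" for i in range(self.nodes_cortical_per_hemi)]

    def subcortical_regions(self) -> list[str]:
        return [f"SC{i + 1}" for i in range(self.nodes_subcortical_per_hemi)]

    def structural_labels(self) -> list[str]:
        regions = self.cortical_regions() + self.subcortical_regions()
        return [f"{h}_{r}" for h in ("L", "R") for r in regions]

    def functional_labels(self) -> list[str]:
        return [f"{h}_{r}" for h in ("L", "R") for r in self.cortical_regions()]


@dataclass
class TrueModel:
    """Ground truth as actually used by the generator."""

    mediators: list[dict]  # modality, region, pgs, a, b, indirect
    direct_effects: dict[str, float]
    total_effects: dict[str, float]
    implied_incremental_r2: dict[str, float]
    outcome_noise_sd: float
    outcome_variance: float
    zero_edge_indices: list[int]  # indices into the upper triangle, or []
    n_structural_nodes: int
    outlier_subjects: dict[str, list[str]]  # stream -> injected subject ids
    seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "TrueModel":
        return cls(**json.loads(Path(path).read_text()))

    def true_mediator_ids(self, modality: str, pgs: str | None = None) -> list[str]:
        return [
            m["region"]
            for m in self.mediators
            if m["modality"] == modality and (pgs is None or m["pgs"] == pgs)
        ]


@dataclass
class Cohort:
    """Generated tables and connectomes sharing one subject roster."""

    phenotypes: pd.DataFrame  # subject, iq, pgs_ea, pgs_gi, age, sex, pc1-4
    surface_area: pd.DataFrame  # subject x cortical region
    thickness: pd.DataFrame
    structural: GroupConnectivity | None
    functional: GroupConnectivity | None

    @property
    def subjects(self) -> list[str]:
        return self.phenotypes["subject"].tolist()


def _covariate_vector(effects: dict[str, float]) -> np.ndarray:
    return np.array([effects.get(c, 0.0) for c in COVARIATE_NAMES])


def _calibrate(config: CohortConfig):
    """Solve direct effects and outcome noise; reject impossible requests."""
    gamma = _covariate_vector(config.covariate_effects.get("mediators", {}))
    delta = _covariate_vector(config.covariate_effects.get("outcome", {}))
    meds = config.true_mediators
    ab = {"EA": 0.0, "GI": 0.0}
    for m in meds:
        ab[m.pgs] += m.a * m.b

    targets = {"EA": config.target_incremental_r2.get("EA", 0.0),
               "GI": config.target_incremental_r2.get("GI", 0.0)}
    if config.direct_effect is None:
        c_prime = {k: np.sqrt(targets[k]) - ab[k] for k in ("EA", "GI")}
        for k, v in c_prime.items():
            if abs(v) >= 1:
                raise ValueError(
                    f"requested incremental R² for {k} unattainable: implied "
                    f"direct effect {v:.3f} is not a valid standardized path"
                )
    else:
        c_prime = {k: float(config.direct_effect.get(k, 0.0)) for k in ("EA", "GI")}

    tau = {k: c_prime[k] + ab[k] for k in ("EA", "GI")}
    if config.direct_effect is None:
        var_y = 1.0  # targets met exactly by construction
    else:
        var_y = 1.0  # explicit paths: outcome normalized to unit variance

    # mediator noise so each mediator latent has unit variance
    med_noise = []
    for m in meds:
        v = 1.0 - m.a**2 - float(gamma @ gamma)
        if v <= 0:
            raise ValueError(
                f"mediator {m.region}: paths and covariate effects exceed unit variance"
            )
        med_noise.append(np.sqrt(v))

    # analytic Var(Y): loadings on the independent primitives
    b_vec = np.array([m.b for m in meds])
    load_cov = delta + b_vec.sum() * gamma  # outcome loading per covariate
    explained = (
        tau["EA"] ** 2
        + tau["GI"] ** 2
        + float(load_cov @ load_cov)
        + float((b_vec**2 * np.array(med_noise) ** 2).sum())
    )
    noise_var = var_y - explained
    if noise_var <= 0:
        raise ValueError(
            f"requested incremental R² unattainable given paths: explained "
            f"variance {explained:.3f} exceeds the outcome variance {var_y:.3f}"
        )
    implied = {k: tau[k] ** 2 / var_y for k in ("EA", "GI")}
    return c_prime, tau, np.array(med_noise), np.sqrt(noise_var), var_y, implied, gamma, delta


def _standardized_covariates(pheno: pd.DataFrame) -> np.ndarray:
    age_z = (pheno["age"].to_numpy() - 46.5) / ((75 - 18) / np.sqrt(12))
    sex_c = 2.0 * pheno["sex"].to_numpy() - 1.0
    pcs = pheno[["pc1", "pc2", "pc3", "pc4"]].to_numpy()
    return np.column_stack([age_z, sex_c, pcs])


def _functional_loadings(config: CohortConfig):
    """Deterministic factor and nuisance loadings for the functional model."""
    fm = config.functional_noise
    labels = config.functional_labels()
    regions = config.cortical_regions()
    isolated = fm.isolated_regions
    if isolated is None:
        isolated = (regions[-1],)
    n_nodes = len(labels)
    net_of_region = {r: i % fm.n_networks for i, r in enumerate(regions)}
    lam = np.zeros((n_nodes, fm.n_networks + 1))
    for i, lab in enumerate(labels):
        region = lab[2:]
        if region in isolated:
            continue
        lam[i, net_of_region[region]] = fm.network_loading
        lam[i, fm.n_networks] = fm.global_loading
    rng = np.random.default_rng([config.seed, _TEMPLATE, 1])
    nu = rng.normal(0.0, fm.nuisance_loading_sd, size=(n_nodes, fm.n_nuisance))
    return lam, nu, list(isolated)


def generate_time_courses(
    config: CohortConfig, subject_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Node-level functional time courses plus the shared nuisance signals.

    Returns ``(signals, nuisance)`` with shapes (n_nodes, T) and
    (n_regressors, T); the nuisance signals are returned separately so that
    the connectivity step can regress them out.  Seeded by the master seed and
    the subject index, so repeated calls are identical.
    """
    fm = config.functional_noise
    if fm.n_timepoints <= 0:
        raise ValueError("n_timepoints must be positive")
    lam, nu, _ = _functional_loadings(config)
    rng = np.random.default_rng([config.seed, _FUNC, subject_index])
    factors = rng.normal(size=(lam.shape[1], fm.n_timepoints))
    nuisance = rng.normal(size=(nu.shape[1], fm.n_timepoints))
    noise = rng.normal(0.0, fm.noise_sd, size=(lam.shape[0], fm.n_timepoints))
    signals = lam @ factors + nu @ nuisance + noise
    return signals, nuisance


def _mediator_latents(config, pheno, cov_std, gamma, med_noise, rng):
    """Latent standardized value of every designated mediator, per subject."""
    n = len(pheno)
    pgs = {"EA": pheno["pgs_ea"].to_numpy(), "GI": pheno["pgs_gi"].to_numpy()}
    latents = np.empty((n, len(config.true_mediators)))
    for j, m in enumerate(config.true_mediators):
        latents[:, j] = (
            m.a * pgs[m.pgs] + cov_std @ gamma + med_noise[j] * rng.normal(size=n)
        )
    return latents


def generate_cohort(config: CohortConfig) -> tuple[Cohort, TrueModel]:
    """Generate a full synthetic cohort and the ground truth it embodies."""
    c_prime, tau, med_noise, noise_sd, var_y, implied, gamma, delta = _calibrate(config)
    n = config.n_subjects
    meds = config.true_mediators

    rng_p = np.random.default_rng([config.seed, _PHENO])
    subjects = [f"S{i + 1:04d}" for i in range(n)]
    pheno = pd.DataFrame(
        {
            "subject": subjects,
            "age": rng_p.uniform(18, 75, n),
            "sex": rng_p.integers(0, 2, n),
            "pc1": rng_p.normal(size=n),
            "pc2": rng_p.normal(size=n),
            "pc3": rng_p.normal(size=n),
            "pc4": rng_p.normal(size=n),
            "pgs_ea": rng_p.normal(size=n),
            "pgs_gi": rng_p.normal(size=n),
        }
    )
    cov_std = _standardized_covariates(pheno)
    latents = _mediator_latents(config, pheno, cov_std, gamma, med_noise, rng_p)

    b_vec = np.array([m.b for m in meds])
    y = (
        latents @ b_vec
        + c_prime["EA"] * pheno["pgs_ea"].to_numpy()
        + c_prime["GI"] * pheno["pgs_gi"].to_numpy()
        + cov_std @ delta
        + noise_sd * rng_p.normal(size=n)
    )
    pheno["iq"] = 100 + 15 * y / np.sqrt(var_y)

    # regional anatomical tables (cortical regions, hemisphere-averaged scale)
    rng_t = np.random.default_rng([config.seed, _TEMPLATE, 0])
    regions = config.cortical_regions()
    sa_base = rng_t.uniform(300, 900, size=len(regions))
    bg_noise = np.sqrt(max(1.0 - float(gamma @ gamma), 1e-6))
    med_idx = {(m.modality, m.region): j for j, m in enumerate(meds)}

    def regional_table(modality: str, base, scale, offset) -> pd.DataFrame:
        vals = np.empty((n, len(regions)))
        for r_i, region in enumerate(regions):
            key = (modality, region)
            if key in med_idx:
                lat = latents[:, med_idx[key]]
            else:
                lat = cov_std @ gamma + bg_noise * rng_p.normal(size=n)
            vals[:, r_i] = (base[r_i] if np.ndim(base) else base) + scale * lat + offset
        df = pd.DataFrame(vals, columns=regions)
        df.insert(0, "subject", subjects)
        return df

    surface_area = regional_table("surface_area", sa_base, 60.0, 0.0)
    thickness = regional_table("thickness", 0.0, 0.16, 2.6)

    # structural connectome
    structural = None
    zero_idx: list[int] = []
    if config.include_structural:
        structural, zero_idx = _generate_structural(config, latents, med_idx)

    # functional connectome via simulated time courses
    functional = None
    if config.include_functional:
        functional = _generate_functional(config, latents, med_idx)

    # outlier injection
    outliers: dict[str, list[str]] = {"anatomical": [], "structural": [], "functional": []}
    if config.outlier_injection > 0:
        rng_o = np.random.default_rng([config.seed, _OUTLIER])
        chosen = rng_o.choice(n, size=min(config.outlier_injection, n), replace=False)
        streams = ["anatomical", "structural", "functional"]
        for k, si in enumerate(chosen):
            stream = streams[k % 3]
            sid = subjects[si]
            if stream == "anatomical":
                cols = surface_area.columns[1:]
                surface_area.loc[si, cols] = surface_area.loc[si, cols] * 1.5
            elif stream == "structural" and structural is not None:
                structural.weights[si] *= 2.0
            elif stream == "functional" and functional is not None:
                functional.weights[si] *= 2.0
            else:  # stream's modality not generated: fall back to the outcome
                stream = "anatomical"
                pheno.loc[si, "iq"] = 100 + 15 * 8
            outliers[stream].append(sid)

    if structural is not None:
        structural = GroupConnectivity(subjects, structural.weights, structural.labels)
    if functional is not None:
        functional = GroupConnectivity(subjects, functional.weights, functional.labels)

    truth = TrueModel(
        mediators=[
            {"modality": m.modality, "region": m.region, "pgs": m.pgs,
             "a": m.a, "b": m.b, "indirect": m.a * m.b}
            for m in meds
        ],
        direct_effects=c_prime,
        total_effects=tau,
        implied_incremental_r2=implied,
        outcome_noise_sd=float(noise_sd),
        outcome_variance=float(var_y),
        zero_edge_indices=zero_idx,
        n_structural_nodes=len(config.structural_labels()),
        outlier_subjects=outliers,
        seed=config.seed,
    )
    cohort = Cohort(
        phenotypes=pheno[
            ["subject", "iq", "pgs_ea", "pgs_gi", "age", "sex", "pc1", "pc2", "pc3", "pc4"]
        ],
        surface_area=surface_area,
        thickness=thickness,
        structural=structural,
        functional=functional,
    )
    return cohort, truth


def _generate_structural(config: CohortConfig, latents, med_idx):
    ewm = config.edge_weight_model
    labels = config.structural_labels()
    n_nodes = len(labels)
    n = config.n_subjects
    iu, ju = np.triu_indices(n_nodes, k=1)
    n_edges = iu.size

    rng_t = np.random.default_rng([config.seed, _TEMPLATE, 2])
    template = np.exp(rng_t.normal(ewm.log_mean, ewm.log_sd, size=n_edges))
    zero = rng_t.random(n_edges) < ewm.zero_fraction
    template[zero] = 0.0

    rng_s = np.random.default_rng([config.seed, _STRUCT])
    weights = np.empty((n, n_nodes, n_nodes), dtype=np.float32)
    # per-node scaling factors from efficiency-mediator latents
    node_region = [lab[2:] for lab in labels]
    eff_meds = [
        (j, m)
        for j, m in enumerate(config.true_mediators)
        if m.modality == "structural_efficiency"
    ]
    for s in range(n):
        edge_w = template * np.exp(ewm.subject_log_sd * rng_s.normal(size=n_edges))
        edge_w[zero] = np.abs(rng_s.normal(0.0, ewm.zero_noise_sd, size=int(zero.sum())))
        mat = np.zeros((n_nodes, n_nodes), dtype=np.float64)
        mat[iu, ju] = edge_w
        mat += mat.T
        for j, m in eff_meds:
            factor = max(1.0 + ewm.kappa * latents[s, j], 0.05)
            sel = np.array([r == m.region for r in node_region])
            mat[sel, :] *= factor
            mat[:, sel] *= factor
            mat[np.ix_(sel, sel)] /= factor  # edges between the two hemis: scale once
        weights[s] = mat.astype(np.float32)
    group = GroupConnectivity([f"S{i + 1:04d}" for i in range(n)], weights, labels)
    return group, np.flatnonzero(zero).tolist()


def _generate_functional(config: CohortConfig, latents, med_idx):
    fm = config.functional_noise
    labels = config.functional_labels()
    n_nodes = len(labels)
    n = config.n_subjects
    lam, nu, _ = _functional_loadings(config)
    eff_meds = [
        (j, m)
        for j, m in enumerate(config.true_mediators)
        if m.modality == "functional_efficiency"
    ]
    node_region = [lab[2:] for lab in labels]
    weights = np.empty((n, n_nodes, n_nodes), dtype=np.float32)
    ewm = config.edge_weight_model
    for s in range(n):
        rng = np.random.default_rng([config.seed, _FUNC, s])
        factors = rng.normal(size=(lam.shape[1], fm.n_timepoints))
        nuisance = rng.normal(size=(nu.shape[1], fm.n_timepoints))
        noise = rng.normal(0.0, fm.noise_sd, size=(n_nodes, fm.n_timepoints))
        lam_s = lam
        if eff_meds:
            lam_s = lam.copy()
            for j, m in eff_meds:
                factor = max(1.0 + ewm.kappa * latents[s, j], 0.05)
                sel = np.array([r == m.region for r in node_region])
                lam_s[sel] *= factor
        signals = lam_s @ factors + nu @ nuisance + noise
        cm = functional_connectivity(signals, nuisance, labels)
        weights[s] = cm.weights.astype(np.float32)
    return GroupConnectivity([f"S{i + 1:04d}" for i in range(n)], weights, labels)


def truth_summary(truth: TrueModel) -> pd.DataFrame:
    """Human-readable table of the true mediators and their paths."""
    rows = [
        {
            "modality": m["modality"],
            "region": m["region"],
            "pgs": m["pgs"],
            "a": m["a"],
            "b": m["b"],
            "indirect": m["indirect"],
        }
        for m in truth.mediators
    ]
    return pd.DataFrame(rows, columns=["modality", "region", "pgs", "a", "b", "indirect"])


# ---------------------------------------------------------------------------
# cohort I/O: phenotypes.csv, surface_area.tsv, thickness.tsv,
# structural/<subject>.tsv, functional/<subject>.tsv, truth.json

def write_cohort(cohort: Cohort, truth: TrueModel | None, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    cohort.surface_area.to_csv(out / "surface_area.tsv", sep="\t", index=False)
    cohort.thickness.to_csv(out / "thickness.tsv", sep="\t", index=False)
    for name, group in (("structural", cohort.structural), ("functional", cohort.functional)):
        if group is None:
            continue
        sub = out / name
        sub.mkdir(exist_ok=True)
        for i, sid in enumerate(group.subjects):
            pd.DataFrame(group.weights[i], columns=group.labels).to_csv(
                sub / f"{sid}.tsv", sep="\t", index=False, float_format="%.6g"
            )
    if truth is not None:
        truth.to_json(out / "truth.json")


def load_cohort(in_dir) -> tuple[Cohort, TrueModel | None]:
    src = Path(in_dir)
    pheno = pd.read_csv(src / "phenotypes.csv")
    sa = pd.read_csv(src / "surface_area.tsv", sep="\t")
    th = pd.read_csv(src / "thickness.tsv", sep="\t")
    subjects = pheno["subject"].astype(str).tolist()

    def read_group(name: str) -> GroupConnectivity | None:
        sub = src / name
        if not sub.is_dir():
            return None
        mats, labels = [], None
        for sid in subjects:
            df = pd.read_csv(sub / f"{sid}.tsv", sep="\t")
            labels = list(df.columns)
            mats.append(df.to_numpy(dtype=np.float32))
        return GroupConnectivity(subjects, np.stack(mats), labels)

    truth = None
    if (src / "truth.json").exists():
        truth = TrueModel.from_json(src / "truth.json")
    return (
        Cohort(pheno, sa, th, read_group("structural"), read_group("functional")),
        truth,
    )
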