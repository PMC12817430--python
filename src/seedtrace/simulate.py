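"""Structured-population genotype simulator with known ground truth.

Generates georeferenced multi-lineage SNP datasets: evolutionary significant
units (ESUs) drift apart under the Balding--Nichols beta model, seeded
populations are founded from finite seed lots (optionally shared between
populations and optionally mixing several ESUs), and technical replicate
pairs carry injected genotyping errors.  Every scenario ships with its truth
(ancestry matrix, lineage frequencies, per-population category) so that
downstream estimators can be validated by recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype_io import GenotypeMatrix, MISSING, write_vcf

CATEGORIES = (
    "natural",
    "seeded_homogeneous",
    "seeded_admixed",
    "seeded_allochthonous",
)


class InvalidConfigError(ValueError):
    """A scenario parameter is outside its admissible range."""


@dataclass(frozen=True)
class ESUSpec:
    """One evolutionary significant unit: a drifted lineage with a range."""

    esu_id: str
    drift: float
    centroid: tuple[float, float]  # (lat, lon) in degrees
    range_radius_km: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 < self.drift < 1.0:
            raise InvalidConfigError(f"drift must be in (0,1), got {self.drift}")
        if self.range_radius_km <= 0:
            raise InvalidConfigError("range_radius_km must be > 0")
        lat, lon = self.centroid
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise InvalidConfigError(f"invalid centroid {self.centroid}")


@dataclass(frozen=True)
class PopulationSpec:
    """One sampled population.

    ``sources`` lists (esu_id, proportion) contributions to each member's
    expected ancestry.  ``founder_size`` > 0 applies a binomial seed-lot
    bottleneck; populations sharing a ``lot_id`` (and founder_size > 0) are
    founded from the same drawn lot.  ``pop_drift`` adds population-level
    Balding--Nichols drift on top of the ESU frequencies, used for natural
    populations so that they are differentiated from one another.
    """

    pop_id: str
    coords: tuple[float, float]
    n_individuals: int
    category: str
    sources: tuple[tuple[str, float], ...]
    founder_size: int = 0
    lot_id: str | None = None
    pop_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidConfigError(f"unknown category {self.category!r}")
        if self.n_individuals < 1:
            raise InvalidConfigError("n_individuals must be >= 1")
        props = [w for _, w in self.sources]
        if any(not 0.0 <= w <= 1.0 for w in props):
            raise InvalidConfigError("source proportions must be in [0,1]")
        if abs(sum(props) - 1.0) > 1e-9:
            raise InvalidConfigError("source proportions must sum to 1")
        if self.category == "natural":
            if len(self.sources) != 1 or self.founder_size != 0:
                raise InvalidConfigError(
                    "natural populations need exactly one source and no bottleneck"
                )
        if not 0.0 <= self.pop_drift < 1.0:
            raise InvalidConfigError("pop_drift must be in [0,1)")


@dataclass(frozen=True)
class ScenarioConfig:
    esus: tuple[ESUSpec, ...]
    populations: tuple[PopulationSpec, ...]
    n_loci: int
    ancestral_freq_bounds: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.0
    replicate_pairs: int = 0
    injected_error_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise InvalidConfigError("n_loci must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidConfigError("missing_rate must be in [0,1)")
        if not 0.0 <= self.injected_error_rate < 1.0:
            raise InvalidConfigError("injected_error_rate must be in [0,1)")
        known = {e.esu_id for e in self.esus}
        for pop in self.populations:
            for esu_id, _ in pop.sources:
                if esu_id not in known:
                    raise InvalidConfigError(
                        f"population {pop.pop_id} references unknown ESU {esu_id}"
                    )


@dataclass
class ScenarioTruth:
    """Ground truth emitted alongside a simulated dataset."""

    esu_ids: list[str]
    individual_ids: list[str]
    pop_of_individual: dict[str, str]
    true_Q: np.ndarray  # individuals x K
    true_P: np.ndarray  # K x loci
    true_category: dict[str, str]
    seed_lot_freqs: dict[str, np.ndarray] = field(default_factory=dict)

    def to_json(self) -> str:
        obj = {
            "esu_ids": self.esu_ids,
            "individual_ids": self.individual_ids,
            "pop_of_individual": self.pop_of_individual,
            "true_Q": np.round(self.true_Q, 10).tolist(),
            "true_P": np.round(self.true_P, 10).tolist(),
            "true_category": self.true_category,
            "seed_lot_freqs": {
                k: np.round(v, 10).tolist() for k, v in self.seed_lot_freqs.items()
            },
        }
        return json.dumps(obj, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioTruth":
        obj = json.loads(text)
        return cls(
            esu_ids=obj["esu_ids"],
            individual_ids=obj["individual_ids"],
            pop_of_individual=obj["pop_of_individual"],
            true_Q=np.asarray(obj["true_Q"], dtype=float),
            true_P=np.asarray(obj["true_P"], dtype=float),
            true_category=obj["true_category"],
            seed_lot_freqs={
                k: np.asarray(v, dtype=float)
                for k, v in obj["seed_lot_freqs"].items()
            },
        )


def draw_ancestral_freqs(
    n_loci: int, bounds: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Draw ancestral allele frequencies i.i.d. uniform on ``bounds``."""
    low, high = bounds
    if not (0.0 < low <= high < 1.0):
        raise InvalidConfigError(f"bounds must satisfy 0 < low <= high < 1, got {bounds}")
    if n_loci < 0:
        raise InvalidConfigError("n_loci must be >= 0")
    return rng.uniform(low, high, size=n_loci)


def draw_esu_freqs(
    ancestral: np.ndarray, drifts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Balding--Nichols lineage frequencies around ``ancestral``.

    For drift F, p_kj ~ Beta(p_j (1-F)/F, (1-p_j)(1-F)/F), so
    E[p_kj] = p_j and Var[p_kj] = F p_j (1-p_j).
    """
    ancestral = np.asarray(ancestral, dtype=float)
    drifts = np.atleast_1d(np.asarray(drifts, dtype=float))
    if np.any(drifts <= 0.0) or np.any(drifts >= 1.0):
        raise InvalidConfigError("drift parameters must lie in (0,1)")
    out = np.empty((drifts.size, ancestral.size))
    for k, f in enumerate(drifts):
        scale = (1.0 - f) / f
        out[k] = rng.beta(ancestral * scale, (1.0 - ancestral) * scale)
    return np.clip(out, 0.0, 1.0)


def _drifted(freqs: np.ndarray, drift: float, rng: np.random.Generator) -> np.ndarray:
    """One extra Balding--Nichols draw (population-level drift); no-op at 0."""
    if drift <= 0.0:
        return freqs
    scale = (1.0 - drift) / drift
    f = np.clip(freqs, 1e-12, 1.0 - 1e-12)
    return np.clip(rng.beta(f * scale, (1.0 - f) * scale), 0.0, 1.0)


def make_seed_lot(
    source_freqs: np.ndarray,
    proportions: np.ndarray,
    founder_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mix ESU frequencies then resample through a finite founder sample.

    The mixture f_j = sum_k w_k p_kj is replaced by x_j / (2 n_f) with
    x_j ~ Binomial(2 n_f, f_j); founder_size 0 disables the bottleneck.
    """
    source_freqs = np.atleast_2d(np.asarray(source_freqs, dtype=float))
    proportions = np.asarray(proportions, dtype=float)
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise InvalidConfigError("mixture weights must sum to 1")
    mixture = proportions @ source_freqs
    if founder_size == 0:
        return mixture
    if founder_size < 0:
        raise InvalidConfigError("founder_size must be >= 0")
    copies = 2 * founder_size
    return rng.binomial(copies, mixture) / copies


def simulate_genotypes(
    true_Q: np.ndarray,
    P: np.ndarray,
    missing_rate: float,
    rng: np.random.Generator,
    individual_ids: list[str] | None = None,
    scaffold_span_bp: int = 1_000_000,
    n_scaffolds: int = 4,
    mean_depth: float = 14.0,
) -> GenotypeMatrix:
    """Binomial genotypes g_ij ~ Binomial(2, sum_k q_ik p_kj) plus annotations.

    Per-site annotations (mean depth, allele balance, quality-per-depth,
    mapping-quality ratio) are drawn from simple configured distributions so
    that the QC filter cascade has something to act on; they carry no signal.
    """
    true_Q = np.asarray(true_Q, dtype=float)
    P = np.asarray(P, dtype=float)
    if true_Q.ndim != 2 or P.ndim != 2 or true_Q.shape[1] != P.shape[0]:
        raise ValueError(f"shape mismatch: Q {true_Q.shape} vs P {P.shape}")
    n, k = true_Q.shape
    j = P.shape[1]
    freqs = true_Q @ P
    dosages = rng.binomial(2, np.clip(freqs, 0.0, 1.0)).astype(np.int8)
    if missing_rate > 0.0:
        mask = rng.random((n, j)) < missing_rate
        dosages[mask] = MISSING

    if individual_ids is None:
        individual_ids = [f"ind{i:04d}" for i in range(n)]

    # Spread loci across scaffolds with sorted unique positions.
    per = int(np.ceil(j / n_scaffolds))
    scaffolds: list[str] = []
    positions: list[int] = []
    for s in range(n_scaffolds):
        count = min(per, j - s * per)
        if count <= 0:
            break
        pos = np.sort(
            rng.choice(np.arange(1, scaffold_span_bp + 1), size=count, replace=False)
        )
        scaffolds.extend([f"scaffold_{s + 1}"] * count)
        positions.extend(int(p) for p in pos)

    depth = rng.negative_binomial(10, 10.0 / (10.0 + mean_depth), size=j).astype(float)
    ab = np.clip(rng.beta(20, 20, size=j), 0.0, 1.0)  # around 0.5 for hets
    qd = rng.gamma(4.0, 0.5, size=j)
    mqr = rng.normal(1.0, 0.1, size=j)
    gt_depth = rng.negative_binomial(
        10, 10.0 / (10.0 + mean_depth), size=(n, j)
    ).astype(np.int32)

    return GenotypeMatrix(
        dosages=dosages,
        individual_ids=list(individual_ids),
        scaffolds=np.asarray(scaffolds, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.full(j, "A", dtype=object),
        alt=np.full(j, "T", dtype=object),
        site_annotations={"MEAN_DP": depth, "AB": ab, "QD": qd, "MQR": mqr},
        genotype_depth=gt_depth,
    )


def _build_truth(config: ScenarioConfig, rng: np.random.Generator):
    """Draw P, per-population sampling frequencies and the truth object."""
    esu_ids = [e.esu_id for e in config.esus]
    esu_index = {e: i for i, e in enumerate(esu_ids)}
    ancestral = draw_ancestral_freqs(config.n_loci, config.ancestral_freq_bounds, rng)
    drifts = np.array([e.drift for e in config.esus])
    P = draw_esu_freqs(ancestral, drifts, rng)

    # Shared seed lots: one draw per lot key.
    lots: dict[str, np.ndarray] = {}
    individual_ids: list[str] = []
    pop_of_individual: dict[str, str] = {}
    q_rows: list[np.ndarray] = []
    sample_freq_rows: list[np.ndarray] = []
    true_category: dict[str, str] = {}
    seed_lot_freqs: dict[str, np.ndarray] = {}

    for pop in config.populations:
        true_category[pop.pop_id] = pop.category
        weights = np.array([w for _, w in pop.sources])
        src_idx = [esu_index[e] for e, _ in pop.sources]
        q = np.zeros(len(esu_ids))
        q[src_idx] = weights
        if pop.founder_size > 0:
            key = pop.lot_id if pop.lot_id is not None else f"__pop__{pop.pop_id}"
            if key not in lots:
                lots[key] = make_seed_lot(P[src_idx], weights, pop.founder_size, rng)
            pop_freq = lots[key]
            seed_lot_freqs[pop.pop_id] = pop_freq
        else:
            pop_freq = weights @ P[src_idx]
        pop_freq = _drifted(pop_freq, pop.pop_drift, rng)
        for i in range(pop.n_individuals):
            ind = f"{pop.pop_id}_{i:02d}"
            individual_ids.append(ind)
            pop_of_individual[ind] = pop.pop_id
            q_rows.append(q)
            sample_freq_rows.append(pop_freq)

    truth = ScenarioTruth(
        esu_ids=esu_ids,
        individual_ids=individual_ids,
        pop_of_individual=pop_of_individual,
        true_Q=np.vstack(q_rows),
        true_P=P,
        true_category=true_category,
        seed_lot_freqs=seed_lot_freqs,
    )
    return truth, np.vstack(sample_freq_rows)


def _inject_errors(
    row: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each called genotype to one of the other two states w.p. ``rate``."""
    out = row.copy()
    called = np.flatnonzero(out != MISSING)
    if rate <= 0.0 or called.size == 0:
        return out
    hit = called[rng.random(called.size) < rate]
    for idx in hit:
        choices = [g for g in (0, 1, 2) if g != out[idx]]
        out[idx] = choices[rng.integers(len(choices))]
    return out


def generate_scenario(config: ScenarioConfig, out_dir: str | Path):
    """Write VCF + metadata + replicate VCFs + truth for one scenario.

    Returns (GenotypeMatrix, ScenarioTruth, dict of written paths).  Fully
    deterministic given ``config.rng_seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    truth, sample_freqs = _build_truth(config, rng)

    n = len(truth.individual_ids)
    # Each individual draws from its own population's sampling frequencies:
    # identity Q against the per-individual frequency rows.  truth.true_Q
    # stores the ESU ancestry, which is what estimators must recover.
    G = simulate_genotypes(
        np.eye(n),
        sample_freqs,
        config.missing_rate,
        rng,
        individual_ids=truth.individual_ids,
    )

    vcf_path = out_dir / "genotypes.vcf"
    write_vcf(G, vcf_path)

    meta_path = out_dir / "metadata.tsv"
    with open(meta_path, "w") as fh:
        fh.write("individual_id\tpop_id\tlatitude\tlongitude\tstatus\n")
        pop_by_id = {p.pop_id: p for p in config.populations}
        for ind in truth.individual_ids:
            pop = pop_by_id[truth.pop_of_individual[ind]]
            status = "natural" if pop.category == "natural" else "unknown"
            fh.write(
                f"{ind}\t{pop.pop_id}\t{pop.coords[0]:.5f}\t{pop.coords[1]:.5f}\t{status}\n"
            )

    rep_paths: list[Path] = []
    if config.replicate_pairs > 0:
        chosen = rng.choice(n, size=min(config.replicate_pairs, n), replace=False)
        rep = G.subset_individuals(sorted(int(c) for c in chosen))
        rep.individual_ids = [f"{i}_rep" for i in rep.individual_ids]
        rep.dosages = np.vstack(
            [
                _inject_errors(row, config.injected_error_rate, rng)
                for row in rep.dosages
            ]
        )
        rep_path = out_dir / "replicates.vcf"
        write_vcf(rep, rep_path)
        rep_paths.append(rep_path)

    truth_path = out_dir / "truth.json"
    truth_path.write_text(truth.to_json())

    config_path = out_dir / "scenario_config.json"
    config_path.write_text(json.dumps(_config_to_dict(config), indent=1, sort_keys=True))

    paths = {
        "vcf": vcf_path,
        "metadata": meta_path,
        "truth": truth_path,
        "config": config_path,
        "replicates": rep_paths,
    }
    return G, truth, paths


def _config_to_dict(config: ScenarioConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [enc(x) for x in obj]
        return obj

    return enc(config)
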