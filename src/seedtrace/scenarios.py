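"""Canned simulation scenarios for validation and demonstration."""

from __future__ import annotations

from .simulate import ESUSpec, PopulationSpec, ScenarioConfig

# Three lineages ~200 km apart; categories cover all four decision outcomes.
_ESU_A = ("A", (46.8, 7.1))
_ESU_B = ("B", (47.5, 9.6))
_ESU_C = ("C", (45.9, 6.0))


def demo_scenario(
    seed: int = 0,
    n_individuals: int = 10,
    n_loci: int = 1000,
    drift: float = 0.2,
    natural_pop_drift: float = 0.1,
    founder_size: int = 25,
    missing_rate: float = 0.02,
) -> ScenarioConfig:
    """Three-ESU scenario with 9 populations covering every category.

    Natural populations carry population-level drift so they are mutually
    differentiated; three seeded populations share one seed lot from ESU A;
    one admixed population mixes A with far-away B; one population is founded
    from C far outside C's range.
    """
    esus = tuple(
        ESUSpec(esu_id=e, drift=drift, centroid=c) for e, c in (_ESU_A, _ESU_B, _ESU_C)
    )

    def pop(pop_id, coords, category, sources, founder=0, lot=None, pdrift=0.0):
        return PopulationSpec(
            pop_id=pop_id,
            coords=coords,
            n_individuals=n_individuals,
            category=category,
            sources=sources,
            founder_size=founder,
            lot_id=lot,
            pop_drift=pdrift,
        )

    populations = (
        pop("natA1", (46.85, 7.00), "natural", (("A", 1.0),), pdrift=natural_pop_drift),
        pop("natA2", (46.70, 7.25), "natural", (("A", 1.0),), pdrift=natural_pop_drift),
        pop("natB1", (47.50, 9.55), "natural", (("B", 1.0),), pdrift=natural_pop_drift),
        pop("natC1", (45.95, 6.05), "natural", (("C", 1.0),), pdrift=natural_pop_drift),
        pop("seedA1", (46.90, 7.10), "seeded_homogeneous", (("A", 1.0),),
            founder=founder_size, lot="lotA"),
        pop("seedA2", (46.75, 7.35), "seeded_homogeneous", (("A", 1.0),),
            founder=founder_size, lot="lotA"),
        pop("seedA3", (46.95, 7.45), "seeded_homogeneous", (("A", 1.0),),
            founder=founder_size, lot="lotA"),
        pop("admixAB", (46.80, 7.15), "seeded_admixed",
            (("A", 0.6), ("B", 0.4)), founder=200, lot="lotAB"),
        pop("allochC", (47.40, 8.90), "seeded_allochthonous", (("C", 1.0),),
            founder=founder_size, lot="lotC"),
    )
    return ScenarioConfig(
        esus=esus,
        populations=populations,
        n_loci=n_loci,
        ancestral_freq_bounds=(0.1, 0.9),
        missing_rate=missing_rate,
        replicate_pairs=2,
        injected_error_rate=0.01,
        rng_seed=seed,
    )


def two_esu_scenario(
    seed: int = 0,
    drift: float = 0.2,
    n_individuals: int = 50,
    n_loci: int = 10_000,
) -> ScenarioConfig:
    """Two natural populations, one per ESU, for F_ST calibration."""
    esus = (
        ESUSpec(esu_id="A", drift=drift, centroid=(46.8, 7.1)),
        ESUSpec(esu_id="B", drift=drift, centroid=(47.5, 9.6)),
    )
    populations = (
        PopulationSpec("popA", (46.8, 7.1), n_individuals, "natural", (("A", 1.0),)),
        PopulationSpec("popB", (47.5, 9.6), n_individuals, "natural", (("B", 1.0),)),
    )
    return ScenarioConfig(
        esus=esus, populations=populations, n_loci=n_loci, rng_seed=seed
    )
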