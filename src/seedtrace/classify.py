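"""Decision rules that turn per-population genomic evidence into a seeding
classification, plus the packaged Swiss evidence fixture.

Categories: natural, seeded_autochthonous_homogeneous, seeded_admixed,
seeded_allochthonous.  The final call is a pure function of the genomic
evidence; collector assessments and habitat-modification records are carried
only for cross-validation summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path

import pandas as pd

EARTH_RADIUS_KM = 6371.0

CATEGORY_NATURAL = "natural"
CATEGORY_HOMOGENEOUS = "seeded_autochthonous_homogeneous"
CATEGORY_ADMIXED = "seeded_admixed"
CATEGORY_ALLOCHTHONOUS = "seeded_allochthonous"


@dataclass
class EsuCatalog:
    """Regional catalogue: which ESUs are autochthonous, and the natural
    non-admixed reference populations (with coordinates) of each ESU."""

    esus: list[str]
    autochthonous: set[str]
    reference_pops: dict[str, list[tuple[str, float, float]]] = field(
        default_factory=dict
    )


@dataclass
class PopulationEvidence:
    pop_id: str
    coords: tuple[float, float]
    source_esus: list[tuple[str, str]]  # (esu, kind in {homogeneous, admixture_component})
    has_homogeneous_source_evidence: bool
    admixed: bool
    allochthonous_sources: set[str]
    collector_assessment: bool = False
    habitat_modification_period: tuple[int, int] | None = None

    def source_names(self) -> list[str]:
        seen: list[str] = []
        for esu, _ in self.source_esus:
            if esu not in seen:
                seen.append(esu)
        return seen


@dataclass
class ClassificationResult:
    pop_id: str
    category: str
    direct_seeding: bool
    rationale: list[str]


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (matches printed figures)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in km between (lat, lon) points in degrees."""
    for lat, lon in (a, b):
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise ValueError(f"invalid coordinates ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def allochthony_test(
    pop_coords: tuple[float, float],
    esu: str,
    catalog: EsuCatalog,
    threshold_km: float = 100.0,
) -> str:
    """'allochthonous' if the ESU is not autochthonous to the region, has no
    natural reference population, or the nearest reference lies more than
    ``threshold_km`` away; otherwise 'autochthonous'."""
    if esu not in catalog.esus:
        raise KeyError(f"unknown ESU {esu!r}")
    if esu not in catalog.autochthonous:
        return "allochthonous"
    refs = catalog.reference_pops.get(esu, [])
    if not refs:
        return "allochthonous"
    nearest = min(great_circle_km(pop_coords, (lat, lon)) for _, lat, lon in refs)
    return "allochthonous" if nearest > threshold_km else "autochthonous"


def build_evidence(
    esu_assignments,
    source_groups,
    catalog: EsuCatalog,
    metadata: pd.DataFrame,
    pop_mean_ancestry: dict[str, dict[str, float]],
    tau: float = 0.10,
    threshold_km: float = 100.0,
) -> list[PopulationEvidence]:
    """Merge per-individual assignments, homogeneous-source groups, and the
    allochthony tests into one evidence record per population.

    ``metadata`` needs columns individual_id, pop_id, latitude, longitude.
    ``pop_mean_ancestry`` maps pop_id -> esu -> mean ancestry.
    """
    pop_of = dict(zip(metadata["individual_id"], metadata["pop_id"]))
    coords = {
        row.pop_id: (float(row.latitude), float(row.longitude))
        for row in metadata.itertuples()
    }
    flagged = source_groups.flagged_populations() if source_groups else set()

    by_pop: dict[str, list] = {}
    for a in esu_assignments:
        pop = pop_of.get(a.individual_id)
        if pop is None:
            raise KeyError(f"individual {a.individual_id!r} has no population mapping")
        by_pop.setdefault(pop, []).append(a)

    out: list[PopulationEvidence] = []
    for pop in sorted(by_pop):
        members = by_pop[pop]
        admixed = any(a.admixed for a in members)
        mean_q = pop_mean_ancestry.get(pop, {})
        sources = [e for e, q in sorted(mean_q.items()) if q >= tau]
        if not sources:  # fall back to the majority assignment
            sources = sorted({a.esu for a in members})
        kinds = [
            (e, "admixture_component" if admixed and len(sources) > 1 else "homogeneous")
            for e in sources
        ]
        alloch = {
            e
            for e in sources
            if allochthony_test(coords[pop], e, catalog, threshold_km) == "allochthonous"
        }
        out.append(
            PopulationEvidence(
                pop_id=pop,
                coords=coords[pop],
                source_esus=kinds,
                has_homogeneous_source_evidence=pop in flagged,
                admixed=admixed,
                allochthonous_sources=alloch,
            )
        )
    return out


def classify_population(ev: PopulationEvidence) -> ClassificationResult:
    """Apply the decision rules in priority order.

    R1 single allochthonous source -> seeded_allochthonous (even if admixed);
    R2 admixed with any allochthonous component -> seeded_admixed;
    R3 homogeneous-source evidence with all sources autochthonous ->
        seeded_autochthonous_homogeneous;
    R4 otherwise (including admixture among autochthonous ESUs only) ->
        natural.  Non-genomic fields never influence the category.
    """
    sources = ev.source_names()
    if not sources:
        raise ValueError(f"population {ev.pop_id}: empty source list")
    rationale: list[str] = []
    if len(sources) == 1 and sources[0] in ev.allochthonous_sources:
        rationale.append("R1: single allochthonous seed source")
        category = CATEGORY_ALLOCHTHONOUS
    elif ev.admixed and ev.allochthonous_sources:
        rationale.append("R2: admixture involving an allochthonous ESU")
        category = CATEGORY_ADMIXED
    elif ev.has_homogeneous_source_evidence and not ev.allochthonous_sources:
        rationale.append("R3: shared homogeneous autochthonous seed source")
        category = CATEGORY_HOMOGENEOUS
    else:
        rationale.append("R4: no genomic seeding evidence")
        category = CATEGORY_NATURAL
    return ClassificationResult(
        pop_id=ev.pop_id,
        category=category,
        direct_seeding=category != CATEGORY_NATURAL,
        rationale=rationale,
    )


def summarize(
    results: list[ClassificationResult], evidence: list[PopulationEvidence]
) -> dict:
    """Summary counts and one-decimal percentages over all populations."""
    ids = [r.pop_id for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate population ids")
    n = len(results)
    ev_by_id = {e.pop_id: e for e in evidence}
    seeded = [r for r in results if r.direct_seeding]
    cat_counts = {
        c: sum(1 for r in results if r.category == c)
        for c in (
            CATEGORY_NATURAL,
            CATEGORY_ALLOCHTHONOUS,
            CATEGORY_ADMIXED,
            CATEGORY_HOMOGENEOUS,
        )
    }
    alloch_any = sum(1 for e in evidence if e.allochthonous_sources)
    collector = sum(1 for e in evidence if e.collector_assessment)
    habitat = [e for e in evidence if e.habitat_modification_period is not None]

    pct = lambda k: round1(100.0 * k / n) if n else float("nan")
    pct_seeded = pct(len(seeded))
    pct_collector = pct(collector)
    summary = {
        "n_populations": n,
        "n_seeded": len(seeded),
        "pct_seeded": pct_seeded,
        "n_natural": cat_counts[CATEGORY_NATURAL],
        "pct_natural": pct(cat_counts[CATEGORY_NATURAL]),
        "n_allochthonous": cat_counts[CATEGORY_ALLOCHTHONOUS],
        "pct_allochthonous": pct(cat_counts[CATEGORY_ALLOCHTHONOUS]),
        "n_admixed_seeded": cat_counts[CATEGORY_ADMIXED],
        "pct_admixed_seeded": pct(cat_counts[CATEGORY_ADMIXED]),
        "n_homogeneous_autochthonous": cat_counts[CATEGORY_HOMOGENEOUS],
        "pct_homogeneous_autochthonous": pct(cat_counts[CATEGORY_HOMOGENEOUS]),
        "n_with_allochthonous_material": alloch_any,
        "pct_with_allochthonous_material": pct(alloch_any),
        "n_collector_flagged": collector,
        "pct_collector_flagged": pct_collector,
        "n_habitat_modification": len(habitat),
        "genomic_minus_collector_pct": round1(abs(pct_seeded - pct_collector)),
    }
    # Years since a 2021 sampling campaign, under three period conventions;
    # the printed mean is not reproducible from the table, so all three are
    # reported (see README).
    if habitat:
        ref_year = 2021
        for name, f in (
            ("start", lambda p: p[0]),
            ("end", lambda p: p[1]),
            ("midpoint", lambda p: (p[0] + p[1]) / 2.0),
        ):
            years = [ref_year - f(e.habitat_modification_period) for e in habitat]
            summary[f"mean_years_since_modification_{name}"] = round1(
                sum(years) / len(years)
            )
    return summary


# ---------------------------------------------------------------------------
# Packaged evidence fixture


def _parse_sources(spec: str) -> list[tuple[str, str]]:
    out = []
    for tok in spec.split(";"):
        tok = tok.strip()
        if not tok:
            continue
        esu, _, kind = tok.partition(":")
        out.append((esu.strip(), kind.strip() or "homogeneous"))
    return out


def load_evidence_fixture(
    evidence_path: str | Path | None = None,
    catalog_path: str | Path | None = None,
) -> tuple[list[PopulationEvidence], EsuCatalog]:
    """Load the packaged Swiss per-population evidence table and regional
    ESU catalogue (or user-supplied files in the same schema)."""
    if evidence_path is None:
        evidence_path = resources.files("seedtrace.data") / "swiss_evidence.tsv"
    if catalog_path is None:
        catalog_path = resources.files("seedtrace.data") / "esu_catalog.tsv"

    cat = pd.read_csv(catalog_path, sep="\t", dtype=str)
    for col in ("esu", "autochthonous"):
        if col not in cat.columns:
            raise ValueError(f"catalog: missing column {col!r}")
    catalog = EsuCatalog(
        esus=list(cat["esu"]),
        autochthonous={
            row.esu for row in cat.itertuples() if row.autochthonous.lower() in ("1", "true", "yes")
        },
    )

    df = pd.read_csv(evidence_path, sep="\t", dtype=str).fillna("")
    required = {
        "pop_id", "lat", "lon", "sources", "allochthonous_sources", "admixed",
        "homogeneous_evidence", "collector_flag", "habitat_years",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"evidence fixture: missing columns {sorted(missing)}")

    evidence: list[PopulationEvidence] = []
    for lineno, row in enumerate(df.itertuples(), start=2):
        try:
            sources = _parse_sources(row.sources)
            alloch = {s.strip() for s in row.allochthonous_sources.split(";") if s.strip()}
            unknown = alloch - {e for e, _ in sources}
            if unknown:
                raise ValueError(f"allochthonous sources not in sources: {unknown}")
            period = None
            if row.habitat_years:
                parts = row.habitat_years.replace("–", "-").split("-")
                y0 = int(parts[0])
                y1 = int(parts[1]) if len(parts) > 1 and parts[1] else y0
                period = (y0, y1)
            evidence.append(
                PopulationEvidence(
                    pop_id=str(row.pop_id),
                    coords=(float(row.lat), float(row.lon)),
                    source_esus=sources,
                    has_homogeneous_source_evidence=row.homogeneous_evidence == "1",
                    admixed=row.admixed == "1",
                    allochthonous_sources=alloch,
                    collector_assessment=row.collector_flag == "1",
                    habitat_modification_period=period,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"evidence fixture line {lineno}: {exc}") from exc
    return evidence, catalog


def write_summary(summary: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for key in sorted(summary):
            fh.write(f"{key}\t{summary[key]}\n")
    return path
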