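"""Hit-triage decision core: quadrant filter, ideal-point Euclidean ranking,
and BOILED-Egg absorption/permeation classification.

The quadrant filter keeps candidates at least as good as the reference
ligand on both axes: docking affinity ≤ reference affinity (more negative
is better) and predicted LD50 ≥ reference LD50 (larger is safer); both
bounds inclusive.  Survivors are ranked by Euclidean distance to a
hypothetical ideal compound,

    dist_i = sqrt((affinity_i − affinity_min)² + (ld50_i − ld50_max)²),

computed verbatim in mixed units (kcal/mol and mol/kg) — smaller distance,
better hit.  An optional z-score normalization mode exists for hygiene but
is OFF by default: the verbatim form is the published convention this
package reproduces.

The BOILED-Egg model classifies compounds in (TPSA, WLogP) space: inside
the yolk ellipse → predicted blood–brain-barrier penetration (BBB); else
inside the white ellipse → passive gastrointestinal absorption (HIA); else
Out.  The yolk wins overlaps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .io_model import CompoundRecord, RankedHit

__all__ = [
    "IdealPoint",
    "EggModel",
    "quadrant_filter",
    "ideal_point",
    "euclidean_distance",
    "euclidean_rank",
    "boiled_egg",
    "run_funnel",
]


@dataclass(frozen=True)
class IdealPoint:
    """The hypothetical best compound: most favorable affinity and LD50."""

    affinity_min: float  # kcal/mol
    ld50_max: float  # mol/kg
    provenance: str = "explicit"  # or "from_set"


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]
    width: float  # full axis along x before rotation
    height: float
    angle_deg: float

    def contains(self, x: float, y: float) -> bool:
        th = math.radians(self.angle_deg)
        dx, dy = x - self.center[0], y - self.center[1]
        u = math.cos(th) * dx + math.sin(th) * dy
        v = -math.sin(th) * dx + math.cos(th) * dy
        return (u / (self.width / 2.0)) ** 2 + (v / (self.height / 2.0)) ** 2 <= 1.0


@dataclass(frozen=True)
class EggModel:
    """Two ellipses in (TPSA, WLogP) space: white = HIA, yolk = BBB."""

    white: Ellipse
    yolk: Ellipse

    @classmethod
    def bundled(cls) -> "EggModel":
        """Load the published two-ellipse parameters shipped with the package."""
        raw = resources.files("hitfunnel.data").joinpath("boiled_egg.json").read_text()
        d = json.loads(raw)

        def ell(key):
            e = d[key]
            return Ellipse(tuple(e["center"]), e["width"], e["height"], e["angle_deg"])

        return cls(white=ell("white"), yolk=ell("yolk"))


def quadrant_filter(
    records: Sequence[CompoundRecord],
    reference: CompoundRecord,
) -> list[CompoundRecord]:
    """Keep candidates with affinity ≤ reference and LD50 ≥ reference.

    Bounds are inclusive; the reference itself is excluded from candidates.
    Input order is preserved.  A candidate without an LD50 is an error.
    """
    if reference.ld50 is None:
        raise ValueError("reference compound needs affinity and ld50")
    out = []
    for rec in records:
        if rec.id == reference.id:
            continue
        if rec.ld50 is None:
            raise ValueError(f"candidate {rec.id} is missing ld50")
        if rec.affinity <= reference.affinity and rec.ld50 >= reference.ld50:
            out.append(rec)
    return out


def ideal_point(
    records: Sequence[CompoundRecord],
    explicit: Optional[tuple[float, float]] = None,
) -> IdealPoint:
    """Componentwise best point: min affinity, max LD50 (or pass-through).

    ``explicit=(affinity_min, ld50_max)`` overrides the set scan — used when
    the ideal is defined over a larger pool than the ranked subset.
    """
    if explicit is not None:
        return IdealPoint(explicit[0], explicit[1], provenance="explicit")
    if not records:
        raise ValueError("ideal point of an empty set is undefined")
    for rec in records:
        if rec.ld50 is None:
            raise ValueError(f"record {rec.id} is missing ld50")
    return IdealPoint(
        affinity_min=min(r.affinity for r in records),
        ld50_max=max(r.ld50 for r in records),
        provenance="from_set",
    )


def euclidean_distance(record: CompoundRecord, ideal: IdealPoint) -> float:
    """Mixed-unit ideal-point distance in (affinity, LD50) space."""
    if record.ld50 is None:
        raise ValueError(f"record {record.id} is missing ld50")
    return math.hypot(record.affinity - ideal.affinity_min, record.ld50 - ideal.ld50_max)


def euclidean_rank(
    records: Sequence[CompoundRecord],
    ideal: IdealPoint,
    normalize: bool = False,
    egg: Optional["EggModel"] = None,
) -> list[RankedHit]:
    """Rank records by ascending ideal-point distance; ties break by id.

    ``normalize=True`` z-scores both axes (and the ideal point) before the
    distance — a unit-hygiene mode, not the published convention.  Region
    labels come from each record's annotation when present, otherwise from
    the egg model when WLogP/TPSA are available.
    """
    if not records:
        raise ValueError("cannot rank an empty record set")
    if normalize:
        aff = np.array([r.affinity for r in records], dtype=float)
        ld = np.array([r.ld50 for r in records], dtype=float)
        mu_a, sd_a = aff.mean(), aff.std() or 1.0
        mu_l, sd_l = ld.mean(), ld.std() or 1.0
        dists = {
            r.id: math.hypot(
                (r.affinity - mu_a) / sd_a - (ideal.affinity_min - mu_a) / sd_a,
                (r.ld50 - mu_l) / sd_l - (ideal.ld50_max - mu_l) / sd_l,
            )
            for r in records
        }
    else:
        dists = {r.id: euclidean_distance(r, ideal) for r in records}
    ordered = sorted(records, key=lambda r: (dists[r.id], r.id))
    hits = []
    for pos, rec in enumerate(ordered, start=1):
        region = rec.region
        if region is None and egg is not None and rec.wlogp is not None and rec.tpsa is not None:
            region = boiled_egg(rec.wlogp, rec.tpsa, egg)
        hits.append(RankedHit(record=rec, distance=dists[rec.id], rank=pos,
                              region=region, pgp=rec.pgp_substrate))
    return hits


def boiled_egg(wlogp: float, tpsa: float, model: Optional[EggModel] = None) -> str:
    """Classify a compound as 'BBB' (yolk), 'HIA' (white) or 'Out'."""
    if model is None:
        model = EggModel.bundled()
    if model.yolk.contains(tpsa, wlogp):
        return "BBB"
    if model.white.contains(tpsa, wlogp):
        return "HIA"
    return "Out"


def run_funnel(
    records: Sequence[CompoundRecord],
    reference: CompoundRecord,
    explicit_ideal: Optional[tuple[float, float]] = None,
    structures: Optional[dict] = None,
    catalogs: Optional[Sequence] = None,
    dedup_by_structure: bool = False,
    egg: Optional[EggModel] = None,
) -> tuple[list[RankedHit], dict]:
    """Run the full triage funnel and report per-stage counts.

    Stages: deduplicate → qualitative drug-likeness gate (only when
    structures are available) → quadrant filter vs the reference → ideal
    point → Euclidean ranking → region/P-gp annotation.  Returns
    ``(ranked_hits, report)``; an empty post-filter set yields an empty
    ranking and a warning in the report rather than an error.
    """
    from .chem_filters import deduplicate, qualitative_pass

    report: dict = {"stages": {}, "warnings": []}
    report["stages"]["input"] = len(records)

    unique, n_dup = deduplicate(records, by_structure=dedup_by_structure)
    report["stages"]["after_dedup"] = len(unique)
    report["n_duplicates"] = n_dup

    if structures:
        kept = []
        for rec in unique:
            mol = structures.get(rec.id)
            if mol is None:
                kept.append(rec)
                continue
            ok, reasons = qualitative_pass(mol, catalogs=catalogs)
            if ok:
                kept.append(rec)
        unique = kept
    report["stages"]["after_qualitative"] = len(unique)

    candidates = quadrant_filter(unique, reference)
    report["stages"]["after_quadrant"] = len(candidates)
    report["reference"] = {"id": reference.id, "affinity": reference.affinity,
                           "ld50": reference.ld50}

    if not candidates:
        report["warnings"].append("no candidates survive the quadrant filter")
        return [], report

    ideal = ideal_point(candidates, explicit=explicit_ideal)
    report["ideal_point"] = {"affinity_min": ideal.affinity_min,
                             "ld50_max": ideal.ld50_max,
                             "provenance": ideal.provenance}
    hits = euclidean_rank(candidates, ideal, egg=egg or EggModel.bundled())
    report["stages"]["ranked"] = len(hits)
    return hits, report
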