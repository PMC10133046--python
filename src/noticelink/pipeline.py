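"""Linkage orchestration and surveillance aggregation.

Each notice is resolved in one of two ways.  If it carries a device
directory identifier that exists in the registry, the link is *direct* and
the nomenclature code is read straight off the registry row.  Otherwise the
two-phase entity-resolution path runs: a manufacturer block is formed
(cosine or named-entity method) and the best-scoring device within the
block is accepted against the descending threshold schedule.  The link
table preserves notice order and is deterministic given inputs and
configuration.

``summarize`` aggregates linked notices into the counts a surveillance
dashboard shows: totals, per-year histogram, per-nomenclature-prefix counts
at a chosen level, and per-manufacturer counts, under optional filters.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import sparse

from . import manufacturer_match
from .device_match import ThresholdSchedule, find_best_device
from .emdn import parse_emdn
from .manufacturer_match import (
    DEFAULT_COS_THRESHOLD,
    ManufacturerBlock,
    build_tfidf,
    preprocess_manufacturer,
)
from .records_io import DeviceRecord, LinkResult, NoticeRecord
from .textprep import normalize

__all__ = [
    "ResolverConfig",
    "RegistryIndex",
    "Resolver",
    "resolve_all",
    "SurveillanceSummary",
    "summarize",
    "UNASSIGNED",
]

logger = logging.getLogger(__name__)

#: Reserved nomenclature bucket for notices without an assigned code.
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ResolverConfig:
    """Knobs for the two-phase resolution."""

    method: str = "cos"  # "cos" | "ner"
    cos_threshold: float = DEFAULT_COS_THRESHOLD
    schedule: ThresholdSchedule = field(default_factory=ThresholdSchedule)


class RegistryIndex:
    """Registry indexed by progressive id and by canonical manufacturer.

    Duplicate progressive ids keep the first row.  One canonical
    manufacturer name (normalized, suffix-stripped) maps to every device
    registered under any raw variant of that name.
    """

    def __init__(self, devices: Sequence[DeviceRecord]):
        self.devices = list(devices)
        self.by_id: dict[str, DeviceRecord] = {}
        self.by_manufacturer: dict[str, list[DeviceRecord]] = {}
        self._device_norms: dict[str, list[tuple[str, str]]] = {}
        for device in self.devices:
            self.by_id.setdefault(device.progressive_id, device)
            canonical = preprocess_manufacturer(device.manufacturer)
            self.by_manufacturer.setdefault(canonical, []).append(device)
            self._device_norms.setdefault(canonical, []).append(
                (normalize(device.commercial_name), normalize(device.catalogue_code))
            )
        self.manufacturers: list[str] = list(self.by_manufacturer)

    def candidates_for(
        self, canonical_names: set[str]
    ) -> tuple[list[DeviceRecord], list[tuple[str, str]]]:
        devices: list[DeviceRecord] = []
        norms: list[tuple[str, str]] = []
        for name in canonical_names:
            devices.extend(self.by_manufacturer.get(name, ()))
            norms.extend(self._device_norms.get(name, ()))
        return devices, norms


class Resolver:
    """Resolves notices against a registry with a fixed configuration.

    For the cosine method the TF-IDF document universe is the union of the
    unique canonical manufacturer names from the registry and from the
    notice set, so query and corpus weights are consistent; call
    :meth:`fit` with the notices before resolving.
    """

    def __init__(self, registry: RegistryIndex, config: Optional[ResolverConfig] = None):
        self.registry = registry
        self.config = config or ResolverConfig()
        if self.config.method not in ("cos", "ner"):
            raise ValueError(f"unknown method {self.config.method!r}")
        self._model: Optional[manufacturer_match.TfidfModel] = None
        self._registry_matrix: Optional[sparse.csr_matrix] = None
        self._registry_entities: Optional[list[str]] = None
        self._raw_by_canonical: dict[str, str] = {}
        for device in registry.devices:
            self._raw_by_canonical.setdefault(
                preprocess_manufacturer(device.manufacturer), device.manufacturer
            )

    def fit(self, notices: Sequence[NoticeRecord] = ()) -> "Resolver":
        if self.config.method == "cos":
            corpus = list(dict.fromkeys(
                self.registry.manufacturers
                + [preprocess_manufacturer(n.manufacturer) for n in notices]
            ))
            self._model = build_tfidf(corpus)
            self._registry_matrix = self._model.matrix(self.registry.manufacturers)
        else:
            self._registry_entities = [
                normalize(manufacturer_match.extract_named_entity(
                    self._raw_by_canonical[name]))
                for name in self.registry.manufacturers
            ]
        return self

    # -- phase 1 -----------------------------------------------------------
    def block(self, notice: NoticeRecord) -> ManufacturerBlock:
        if self.config.method == "cos":
            if self._model is None:
                self.fit()
            return manufacturer_match.block_by_cosine(
                preprocess_manufacturer(notice.manufacturer),
                self._model,
                self.registry.manufacturers,
                threshold=self.config.cos_threshold,
                registry_matrix=self._registry_matrix,
            )
        if self._registry_entities is None:
            self.fit()
        return manufacturer_match.block_by_ner(
            notice.manufacturer,
            self.registry.manufacturers,
            registry_entities=self._registry_entities,
        )

    # -- full resolution ---------------------------------------------------
    def resolve(self, notice: NoticeRecord) -> LinkResult:
        # Case 1: the directory identifier is present — direct lookup.
        if notice.bdrmd:
            device = self.registry.by_id.get(notice.bdrmd)
            if device is None:
                return LinkResult(
                    reference_number=notice.reference_number,
                    provenance="unmatched",
                    failure_reason="no_bdrmd_in_registry",
                )
            return LinkResult(
                reference_number=notice.reference_number,
                provenance="direct",
                device_id=device.progressive_id,
                emdn_code=device.emdn_code or None,
                matched_manufacturer=device.manufacturer,
            )
        # Case 2: two-phase entity resolution.
        block = self.block(notice)
        if not block.matched:
            return LinkResult(
                reference_number=notice.reference_number,
                provenance="unmatched",
                failure_reason=block.reason if block.reason == "oov" else "no_block",
            )
        candidates, norms = self.registry.candidates_for(block.matched)
        match = find_best_device(
            notice, candidates, self.config.schedule, device_norms=norms
        )
        if match is None:
            return LinkResult(
                reference_number=notice.reference_number,
                provenance="unmatched",
                failure_reason="below_floor",
            )
        device = self.registry.by_id[match.device_id]
        return LinkResult(
            reference_number=notice.reference_number,
            provenance="er",
            device_id=match.device_id,
            emdn_code=device.emdn_code or None,
            score=match.score,
            accepted_threshold=match.accepted_threshold,
            matched_manufacturer=device.manufacturer,
        )


def resolve_all(
    notices: Sequence[NoticeRecord],
    registry: RegistryIndex,
    config: Optional[ResolverConfig] = None,
) -> list[LinkResult]:
    """Resolve every notice in order; logs per-provenance tallies."""
    start = time.perf_counter()
    resolver = Resolver(registry, config).fit(notices)
    links = [resolver.resolve(notice) for notice in notices]
    tallies = {"direct": 0, "er": 0, "unmatched": 0}
    for link in links:
        tallies[link.provenance] += 1
    logger.info(
        "resolved %d notices in %.1fs: %d direct, %d er, %d unmatched",
        len(links), time.perf_counter() - start,
        tallies["direct"], tallies["er"], tallies["unmatched"],
    )
    return links


@dataclass
class SurveillanceSummary:
    """Aggregated counts over the notices passing the active filter."""

    total_notices: int
    counts_by_year: dict[int, int]
    counts_by_emdn_prefix: dict[str, int]
    counts_by_manufacturer: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "total_notices": self.total_notices,
            "counts_by_year": {str(k): v for k, v in sorted(self.counts_by_year.items())},
            "counts_by_emdn_prefix": dict(sorted(self.counts_by_emdn_prefix.items())),
            "counts_by_manufacturer": dict(sorted(self.counts_by_manufacturer.items())),
        }


def _emdn_bucket(raw_code: Optional[str], level: int) -> str:
    if not raw_code:
        return UNASSIGNED
    try:
        code = parse_emdn(raw_code)
    except Exception:
        return UNASSIGNED
    return code.prefix_at(level)


def summarize(
    links: Sequence[LinkResult],
    notices: Sequence[NoticeRecord],
    emdn_level: int = 1,
    year_range: Optional[tuple[int, int]] = None,
    emdn_prefix: Optional[str] = None,
    manufacturer_contains: Optional[str] = None,
) -> SurveillanceSummary:
    """Aggregate *links* (aligned to *notices* by reference number).

    Filters: an inclusive *year_range*, a nomenclature *emdn_prefix* (the
    assigned code must start with it) and a case-insensitive
    *manufacturer_contains* substring.  Unmatched or code-less notices fall
    into the reserved ``unassigned`` bucket and are excluded by any
    prefix filter.
    """
    if not 1 <= emdn_level <= 4:
        raise ValueError("emdn_level must be in 1..4")
    by_ref = {link.reference_number: link for link in links}
    years: dict[int, int] = {}
    prefixes: dict[str, int] = {}
    manufacturers: dict[str, int] = {}
    total = 0
    wanted_prefix = emdn_prefix.strip().upper() if emdn_prefix else None
    wanted_sub = manufacturer_contains.lower() if manufacturer_contains else None
    for notice in notices:
        link = by_ref.get(notice.reference_number)
        code = link.emdn_code if link else None
        manufacturer = (
            link.matched_manufacturer
            if link and link.matched_manufacturer
            else notice.manufacturer
        )
        if year_range is not None:
            if notice.date is None or not year_range[0] <= notice.date.year <= year_range[1]:
                continue
        if wanted_prefix is not None:
            if not code or not code.strip().upper().startswith(wanted_prefix):
                continue
        if wanted_sub is not None and wanted_sub not in manufacturer.lower():
            continue
        total += 1
        if notice.date is not None:
            years[notice.date.year] = years.get(notice.date.year, 0) + 1
        bucket = _emdn_bucket(code, emdn_level)
        prefixes[bucket] = prefixes.get(bucket, 0) + 1
        manufacturers[manufacturer] = manufacturers.get(manufacturer, 0) + 1
    return SurveillanceSummary(
        total_notices=total,
        counts_by_year=years,
        counts_by_emdn_prefix=prefixes,
        counts_by_manufacturer=manufacturers,
    )
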