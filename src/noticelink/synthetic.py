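"""Synthetic registry/notice generator with known ground truth.

Every pipeline stage can be exercised offline: the generator builds a
hierarchical nomenclature catalog, a device registry (optionally with the
same device registered twice under distinct progressive numbers), and a
notice set in which each notice derives from exactly one registry row.
Name corruption — token shuffling, legal-suffix variants, per-character
typos, in that fixed order — is parameterized so linkage accuracy can be
studied as a function of noise.  Identical seed and configuration give
byte-identical datasets.
"""

from __future__ import annotations

import csv
import datetime as _dt
import random
import string
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .emdn import EMDNCode, parse_emdn
from .records_io import DeviceRecord, NoticeRecord

__all__ = [
    "GeneratorConfig",
    "NoticeTruth",
    "GroundTruth",
    "generate_catalog",
    "generate_registry",
    "generate_notices",
    "generate_dataset",
    "write_truth",
    "read_truth",
]

# Bundled lexicons: no external download, no overlap with legal suffixes.
_MANUFACTURER_WORDS = (
    "acme", "apex", "astra", "atlas", "aurora", "axiom", "beacon", "bella",
    "bio", "borea", "calder", "cardio", "cedar", "centra", "clari", "cobalt",
    "corto", "delta", "dental", "derma", "echo", "elan", "ember", "evo",
    "falcon", "fenix", "fluent", "forte", "gamma", "gento", "halo", "harbor",
    "helio", "ibero", "imaging", "ionic", "iris", "juno", "kappa", "kinet",
    "lambda", "lumen", "lyra", "magna", "medex", "medika", "meridian", "micro",
    "mira", "nexo", "nimbus", "nova", "omega", "onda", "optic", "orion",
    "ortho", "pharma", "pico", "pluto", "polar", "prima", "pulse", "quanta",
    "rapid", "raven", "rigel", "sanita", "sigma", "silva", "solara", "sonic",
    "stella", "summit", "surgical", "tecno", "terra", "titan", "ultra",
    "valor", "vega", "verde", "vital", "zenith", "zephyr",
)
_DEVICE_WORDS = (
    "ablation", "access", "adapter", "analyzer", "anchor", "balloon", "basket",
    "blade", "cable", "cannula", "cartridge", "catheter", "clamp", "clip",
    "connector", "console", "cuff", "defibrillator", "dilator", "drain",
    "dressing", "driver", "electrode", "endoscope", "filter", "fixation",
    "forceps", "frame", "generator", "graft", "guide", "guidewire", "handle",
    "implant", "infusion", "injector", "introducer", "kit", "lancet", "lead",
    "lens", "ligature", "line", "marker", "mask", "mesh", "module", "monitor",
    "needle", "occluder", "pacemaker", "pad", "patch", "plate", "port",
    "probe", "prosthesis", "pump", "reamer", "regulator", "reservoir",
    "retractor", "ring", "scaffold", "scanner", "scope", "screw", "sealant",
    "sensor", "set", "shunt", "sleeve", "spacer", "splint", "stapler",
    "stent", "stimulator", "stylet", "suture", "syringe", "system", "tip",
    "tube", "valve", "ventilator", "wire", "adaptive", "advanced", "compact",
    "digital", "dual", "flexible", "micro", "mobile", "portable", "precision",
    "rapid", "smart", "sterile", "ultra",
)
_SUFFIX_STYLES = (
    ("spa", "S.p.A."), ("srl", "S.r.l."), ("gmbh", "GmbH"), ("ag", "AG"),
    ("sa", "SA"), ("inc", "Inc"), ("ltd", "Ltd"), ("llc", "LLC"),
    ("bv", "BV"), ("nv", "NV"), ("plc", "PLC"), ("sarl", "Sarl"),
)
_ACTIONS = ("recall", "update", "suspension of use", "safety information")
_NOTICE_TYPES = ("MD", "IVD", "active implantable MD")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic world."""

    n_manufacturers: int = 50
    devices_per_manufacturer: tuple[int, int] = (2, 8)
    emdn_catalog_size: tuple[int, ...] = (6, 4, 3, 2)  # per-level branching
    bdrmd_fraction: float = 0.32
    typo_rate: float = 0.0
    suffix_variant_prob: float = 0.0
    token_shuffle_prob: float = 0.0
    duplicate_registration_prob: float = 0.0
    notice_count: int = 200
    year_range: tuple[int, int] = (2009, 2021)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bdrmd_fraction", "typo_rate", "suffix_variant_prob",
                     "token_shuffle_prob", "duplicate_registration_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_manufacturers <= 0 or self.notice_count < 0:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class NoticeTruth:
    """Ground truth for one generated notice."""

    reference_number: str
    true_progressive_id: str
    true_emdn: str
    corruption_ops: tuple[str, ...] = ()


@dataclass
class GroundTruth:
    """Per-notice truth table for a generated dataset."""

    entries: list[NoticeTruth] = field(default_factory=list)

    def by_reference(self) -> dict[str, NoticeTruth]:
        return {e.reference_number: e for e in self.entries}


def generate_catalog(
    sizes: Sequence[int], rng: random.Random
) -> list[EMDNCode]:
    """Build a synthetic hierarchical catalog and return its leaf codes.

    ``sizes[0]`` categories (distinct letters), then for each node at level
    *k*, ``sizes[k]`` children labelled with distinct two-digit pairs from
    01 to 99.  At most four levels are generated; every leaf parses under
    the code grammar.
    """
    if not sizes or any(s <= 0 for s in sizes):
        raise ValueError("catalog sizes must be positive")
    if len(sizes) > 4:
        raise ValueError("catalog depth is capped at 4 levels")
    letters = rng.sample(string.ascii_uppercase, min(sizes[0], 26))
    codes = sorted(letters)
    for branching in sizes[1:]:
        next_codes = []
        for prefix in codes:
            pairs = rng.sample(range(1, 100), min(branching, 99))
            next_codes.extend(f"{prefix}{p:02d}" for p in sorted(pairs))
        codes = next_codes
    return [parse_emdn(c) for c in codes]


def _styled_suffix(rng: random.Random) -> str:
    return rng.choice(_SUFFIX_STYLES)[1]


def _unique_name(rng: random.Random, words: Sequence[str], n_tokens: tuple[int, int],
                 taken: set[frozenset]) -> list[str]:
    # reject names whose token set is a subset/superset of an existing one,
    # so fuzzy scores of distinct entities never tie at 100
    for _ in range(1000):
        k = rng.randint(*n_tokens)
        tokens = rng.sample(words, k)
        tokset = frozenset(tokens)
        if any(tokset <= other or other <= tokset for other in taken):
            continue
        taken.add(tokset)
        return tokens
    raise RuntimeError("could not generate a distinct name; widen the lexicon")


def generate_registry(
    config: GeneratorConfig,
    catalog: Sequence[EMDNCode],
    rng: random.Random,
) -> list[DeviceRecord]:
    """Generate registry rows; duplicates re-register a device verbatim.

    Manufacturer names are two distinct lexicon tokens plus a styled legal
    suffix; commercial names are 2..5 tokens, never in a subset relation
    within a manufacturer; catalogue codes are unique alphanumerics.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    records: list[DeviceRecord] = []
    next_id = 1_000_001
    pairs = [(a, b) for a in _MANUFACTURER_WORDS for b in _MANUFACTURER_WORDS if a < b]
    if config.n_manufacturers > len(pairs):
        raise ValueError("too many manufacturers for the bundled lexicon")
    name_pairs = rng.sample(pairs, config.n_manufacturers)
    seen_codes: set[str] = set()
    for a, b in name_pairs:
        manufacturer = f"{a.title()} {b.title()} {_styled_suffix(rng)}"
        n_devices = rng.randint(*config.devices_per_manufacturer)
        taken: set[frozenset] = set()
        for _ in range(n_devices):
            tokens = _unique_name(rng, _DEVICE_WORDS, (2, 5), taken)
            commercial = " ".join(t.title() for t in tokens)
            while True:
                code = "".join(
                    rng.choices(string.ascii_uppercase + string.digits,
                                k=rng.randint(4, 10))
                )
                if code not in seen_codes:
                    seen_codes.add(code)
                    break
            emdn_code = rng.choice(catalog).raw
            base = DeviceRecord(
                progressive_id=str(next_id),
                manufacturer=manufacturer,
                catalogue_code=code,
                commercial_name=commercial,
                device_type=rng.choice(_NOTICE_TYPES),
                emdn_code=emdn_code,
            )
            next_id += 1
            records.append(base)
            if rng.random() < config.duplicate_registration_prob:
                records.append(replace(base, progressive_id=str(next_id)))
                next_id += 1
    return records


# -- corruption operators (fixed order: shuffle -> suffix ops -> typos) -----

def _shuffle_tokens(text: str, prob: float, rng: random.Random,
                    ops: list[str]) -> str:
    tokens = text.split()
    if len(tokens) > 1 and rng.random() < prob:
        rng.shuffle(tokens)
        ops.append("shuffle")
        return " ".join(tokens)
    return text


def _suffix_variant(name: str, prob: float, rng: random.Random,
                    ops: list[str]) -> str:
    if rng.random() >= prob:
        return name
    tokens = name.split()
    bare_last = "".join(ch for ch in tokens[-1] if ch.isalnum()).lower()
    has_suffix = any(bare_last == s for s, _ in _SUFFIX_STYLES)
    action = rng.choice(["drop", "swap", "add"])
    if action == "drop" and has_suffix and len(tokens) > 1:
        tokens.pop()
        ops.append("suffix_drop")
    elif action == "swap" and has_suffix:
        tokens[-1] = _styled_suffix(rng)
        ops.append("suffix_swap")
    else:
        tokens.append(_styled_suffix(rng))
        ops.append("suffix_add")
    return " ".join(tokens)


def _typos(text: str, rate: float, rng: random.Random, ops: list[str]) -> str:
    if rate <= 0:
        return text
    out: list[str] = []
    changed = False
    for ch in text:
        if rng.random() < rate:
            changed = True
            kind = rng.choice(["sub", "ins", "del"])
            if kind == "sub":
                out.append(rng.choice(string.ascii_lowercase))
            elif kind == "ins":
                out.append(ch)
                out.append(rng.choice(string.ascii_lowercase))
            # "del": drop the character
        else:
            out.append(ch)
    if changed:
        ops.append("typo")
    return "".join(out)


def _corrupt(text: str, config: GeneratorConfig, rng: random.Random,
             ops: list[str], suffix_ops: bool = False) -> str:
    text = _shuffle_tokens(text, config.token_shuffle_prob, rng, ops)
    if suffix_ops:
        text = _suffix_variant(text, config.suffix_variant_prob, rng, ops)
    return _typos(text, config.typo_rate, rng, ops)


def generate_notices(
    registry: Sequence[DeviceRecord],
    config: GeneratorConfig,
    rng: random.Random,
) -> tuple[list[NoticeRecord], GroundTruth]:
    """Sample one true registry row per notice and corrupt its names.

    The identifier is included with probability ``bdrmd_fraction``; the
    notice's commercial-name field carries the device's commercial name
    followed by its catalogue code, mirroring how scraped notices often
    embed the model specification.
    """
    if not registry:
        raise ValueError("registry must be non-empty")
    notices: list[NoticeRecord] = []
    truth = GroundTruth()
    y0, y1 = config.year_range
    for i in range(config.notice_count):
        device = rng.choice(registry)
        ops: list[str] = []
        manufacturer = _corrupt(device.manufacturer, config, rng, ops, suffix_ops=True)
        device_name = _corrupt(device.commercial_name, config, rng, ops)
        commercial = _corrupt(
            f"{device.commercial_name} {device.catalogue_code}", config, rng, ops
        )
        bdrmd = device.progressive_id if rng.random() < config.bdrmd_fraction else None
        date = _dt.date(rng.randint(y0, y1), rng.randint(1, 12), rng.randint(1, 28))
        ref = f"SN-{i + 1:06d}"
        notices.append(NoticeRecord(
            reference_number=ref,
            manufacturer=manufacturer,
            device=device_name,
            commercial_name=commercial,
            notice_type=device.device_type,
            action=rng.choice(_ACTIONS),
            date=date,
            bdrmd=bdrmd,
        ))
        truth.entries.append(NoticeTruth(
            reference_number=ref,
            true_progressive_id=device.progressive_id,
            true_emdn=device.emdn_code,
            corruption_ops=tuple(ops),
        ))
    return notices, truth


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[list[DeviceRecord], list[NoticeRecord], GroundTruth, list[EMDNCode]]:
    """Convenience wrapper: catalog + registry + notices from one seed."""
    rng = random.Random(config.seed)
    catalog = generate_catalog(config.emdn_catalog_size, rng)
    registry = generate_registry(config, catalog, rng)
    notices, truth = generate_notices(registry, config, rng)
    return registry, notices, truth, catalog


def write_truth(truth: GroundTruth, path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["reference_number", "true_progressive_id", "true_emdn",
                         "corruption_ops"])
        for entry in truth.entries:
            writer.writerow([entry.reference_number, entry.true_progressive_id,
                             entry.true_emdn, "|".join(entry.corruption_ops)])


def read_truth(path: str) -> GroundTruth:
    truth = GroundTruth()
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            truth.entries.append(NoticeTruth(
                reference_number=row["reference_number"],
                true_progressive_id=row["true_progressive_id"],
                true_emdn=row["true_emdn"],
                corruption_ops=tuple(
                    op for op in row["corruption_ops"].split("|") if op
                ),
            ))
    return truth
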