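"""Linkage-quality evaluation against a reference subset, plus the mid-p
McNemar comparison of two methods.

The reference set is the subset of notices that carry a device directory
identifier: that identifier resolves the true registry row, and the
pipeline is re-run with the identifier hidden so every reference notice
goes through entity resolution.  Four criteria are scored per notice:

1. manufacturer — the predicted device's canonical manufacturer equals the
   true device's;
2. identifier — the predicted progressive id equals the true one exactly;
3. nomenclature by level — the predicted code agrees with the true code at
   hierarchy levels 1..4;
4. conditional nomenclature — criterion 3 restricted to notices failing
   criterion 2 (correct category despite the wrong registration row, e.g.
   when the same device is registered twice under different ids).

Unmatched notices count as incorrect on every criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy.stats import binom

from .emdn import agreement_depth, parse_emdn
from .manufacturer_match import preprocess_manufacturer
from .pipeline import RegistryIndex, ResolverConfig, resolve_all
from .records_io import LinkResult, NoticeRecord

__all__ = [
    "ValidationReport",
    "McNemarResult",
    "evaluate",
    "evaluate_with_reference",
    "midp_mcnemar",
]

EMDN_LEVELS = (1, 2, 3, 4)


@dataclass
class ValidationReport:
    """Per-criterion accuracies and the underlying per-item flags."""

    n_reference: int
    manufacturer_accuracy: float
    id_accuracy: float
    emdn_accuracy_by_level: dict[int, float]
    conditional_emdn_accuracy_by_level: dict[int, Optional[float]]
    n_wrong_id: int
    per_item_flags: dict[str, dict[str, bool]] = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_reference": self.n_reference,
            "manufacturer_accuracy": self.manufacturer_accuracy,
            "id_accuracy": self.id_accuracy,
            "emdn_accuracy_by_level": {
                str(k): v for k, v in self.emdn_accuracy_by_level.items()
            },
            "n_wrong_id": self.n_wrong_id,
            "conditional_emdn_accuracy_by_level": {
                str(k): v for k, v in self.conditional_emdn_accuracy_by_level.items()
            },
        }


@dataclass(frozen=True)
class McNemarResult:
    """Discordant counts and the mid-p value of the paired comparison."""

    b: int  # first method correct, second wrong
    c: int  # first method wrong, second correct
    midp: float


def evaluate(
    links: Sequence[LinkResult],
    reference: Sequence[tuple[str, str]],
    registry: RegistryIndex,
) -> ValidationReport:
    """Score *links* against ``(reference_number, true_progressive_id)`` pairs.

    Every true id must resolve in *registry* (its row supplies the true
    manufacturer and nomenclature code).  Links must have been produced
    with the identifier field hidden, otherwise every link is a direct
    lookup and the evaluation is vacuous.
    """
    if not reference:
        raise ValueError("reference set is empty")
    by_ref = {link.reference_number: link for link in links}
    flags: dict[str, dict[str, bool]] = {}
    for ref_number, true_id in reference:
        true_device = registry.by_id.get(true_id)
        if true_device is None:
            raise ValueError(f"reference id {true_id!r} not found in registry")
        link = by_ref.get(ref_number)
        item = {
            "manufacturer": False,
            "id": False,
            **{f"emdn_level_{k}": False for k in EMDN_LEVELS},
        }
        if link is not None and link.provenance != "unmatched" and link.device_id:
            predicted = registry.by_id.get(link.device_id)
            if predicted is not None:
                item["manufacturer"] = (
                    preprocess_manufacturer(predicted.manufacturer)
                    == preprocess_manufacturer(true_device.manufacturer)
                )
                item["id"] = predicted.progressive_id == true_device.progressive_id
                if predicted.emdn_code and true_device.emdn_code:
                    depth = agreement_depth(
                        parse_emdn(predicted.emdn_code), parse_emdn(true_device.emdn_code)
                    )
                    for k in EMDN_LEVELS:
                        item[f"emdn_level_{k}"] = depth >= k
        flags[ref_number] = item

    n = len(flags)
    wrong_id = [ref for ref, item in flags.items() if not item["id"]]
    conditional: dict[int, Optional[float]] = {}
    for k in EMDN_LEVELS:
        if wrong_id:
            conditional[k] = sum(
                flags[ref][f"emdn_level_{k}"] for ref in wrong_id
            ) / len(wrong_id)
        else:
            conditional[k] = None
    return ValidationReport(
        n_reference=n,
        manufacturer_accuracy=sum(i["manufacturer"] for i in flags.values()) / n,
        id_accuracy=sum(i["id"] for i in flags.values()) / n,
        emdn_accuracy_by_level={
            k: sum(i[f"emdn_level_{k}"] for i in flags.values()) / n for k in EMDN_LEVELS
        },
        conditional_emdn_accuracy_by_level=conditional,
        n_wrong_id=len(wrong_id),
        per_item_flags=flags,
    )


def evaluate_with_reference(
    notices: Sequence[NoticeRecord],
    registry: RegistryIndex,
    config: Optional[ResolverConfig] = None,
) -> tuple[ValidationReport, list[LinkResult]]:
    """Run the full evaluation protocol on the identifier-bearing subset.

    Notices carrying an identifier resolvable in *registry* form the
    reference; they are re-resolved with the identifier hidden and scored.
    """
    reference_notices = [
        n for n in notices if n.bdrmd and n.bdrmd in registry.by_id
    ]
    if not reference_notices:
        raise ValueError("no notices carry a registry-resolvable identifier")
    hidden = [
        NoticeRecord(
            reference_number=n.reference_number,
            manufacturer=n.manufacturer,
            device=n.device,
            commercial_name=n.commercial_name,
            notice_type=n.notice_type,
            action=n.action,
            date=n.date,
            bdrmd=None,
        )
        for n in reference_notices
    ]
    links = resolve_all(hidden, registry, config)
    reference = [(n.reference_number, n.bdrmd) for n in reference_notices]
    return evaluate(links, reference, registry), links


def midp_mcnemar(
    flags_a: Sequence[bool], flags_b: Sequence[bool]
) -> McNemarResult:
    """Mid-p McNemar test on paired correctness flags.

    With ``b`` (A correct, B wrong), ``c`` (A wrong, B correct),
    ``n = b + c``, ``m = max(b, c)`` and ``X ~ Binomial(n, 1/2)``, the
    mid-p value is ``min(1, 2 P(X >= m) - P(X = m))``; it is 1 when there
    are no discordant pairs.
    """
    if len(flags_a) != len(flags_b):
        raise ValueError("flag sequences must have equal length")
    b = sum(1 for fa, fb in zip(flags_a, flags_b) if fa and not fb)
    c = sum(1 for fa, fb in zip(flags_a, flags_b) if not fa and fb)
    n = b + c
    if n == 0:
        return McNemarResult(b=b, c=c, midp=1.0)
    m = max(b, c)
    tail = float(binom.sf(m - 1, n, 0.5))  # P(X >= m)
    point = float(binom.pmf(m, n, 0.5))
    return McNemarResult(b=b, c=c, midp=min(1.0, 2.0 * tail - point))
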