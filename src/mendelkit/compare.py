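"""Genotype concordance between two VCF call sets.

Positions are matched on (chrom, pos) only; genotypes at a common position
are compared as unordered multisets of allele *strings* (so the same site
with different ALT encodings still compares correctly), ignoring phase.
Positions where either side's genotype is missing are excluded from the
concordance denominator. The same machinery serves the tumor-vs-germline
use: :func:`private_variants` returns the alt-carrying records unique to
each side.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .errors import ComparisonError
from .records import VariantRecord, VariantSet, chrom_sort_key

__all__ = ["ComparisonResult", "compare_vcfs", "private_variants"]


@dataclass
class ComparisonResult:
    positions_in_common: int
    concordant_genotypes: int
    discordant: list = field(default_factory=list)  # (chrom,pos,gtA,gtB)
    private_to_a: int = 0
    private_to_b: int = 0

    @property
    def concordance_percent(self) -> Optional[float]:
        """Exact concordance percentage; None when no common positions."""
        if self.positions_in_common == 0:
            return None
        return 100.0 * self.concordant_genotypes / self.positions_in_common

    @property
    def concordance_percent_display(self) -> Optional[float]:
        pct = self.concordance_percent
        return None if pct is None else round(pct, 1)


def _pick_sample(vs: VariantSet, sample: Optional[str], label: str) -> str:
    if sample is not None:
        if sample not in vs.samples:
            raise ComparisonError(
                f"sample {sample!r} not present in input {label}"
            )
        return sample
    if len(vs.samples) == 1:
        return vs.samples[0]
    if not vs.samples:
        raise ComparisonError(f"input {label} has no genotype columns")
    raise ComparisonError(
        f"input {label} is multi-sample; specify which sample to compare"
    )


def _genotype_map(vs: VariantSet, sample: str) -> dict:
    """(chrom,pos) -> (record, allele-string multiset or None if missing)."""
    out: dict = {}
    for rec in vs.records:
        key = (rec.chrom, rec.pos)
        if key in out:
            continue  # first record at a position wins
        call = rec.calls[sample]
        if call.allele_indices is None:
            gt = None
        else:
            try:
                gt = Counter(rec.allele_string(i) for i in call.allele_indices)
            except IndexError:
                gt = None  # out-of-range index: treat as missing
        out[key] = (rec, gt)
    return out


def compare_vcfs(
    a: VariantSet,
    b: VariantSet,
    sample_a: Optional[str] = None,
    sample_b: Optional[str] = None,
) -> ComparisonResult:
    """Compare genotypes of two call sets at their common positions.

    Returns counts of common positions, concordant genotypes, the discordant
    site list and the number of positions private to each side. Sites where
    either genotype is missing are dropped from the comparison denominator.
    """
    sample_a = _pick_sample(a, sample_a, "A")
    sample_b = _pick_sample(b, sample_b, "B")
    map_a = _genotype_map(a, sample_a)
    map_b = _genotype_map(b, sample_b)

    common = sorted(
        set(map_a) & set(map_b),
        key=lambda k: (chrom_sort_key(k[0]), k[1]),
    )
    result = ComparisonResult(
        positions_in_common=0,
        concordant_genotypes=0,
        private_to_a=len(set(map_a) - set(map_b)),
        private_to_b=len(set(map_b) - set(map_a)),
    )
    for key in common:
        _, gt_a = map_a[key]
        _, gt_b = map_b[key]
        if gt_a is None or gt_b is None:
            continue
        result.positions_in_common += 1
        if gt_a == gt_b:
            result.concordant_genotypes += 1
        else:
            result.discordant.append((
                key[0], key[1],
                "/".join(sorted(gt_a.elements())),
                "/".join(sorted(gt_b.elements())),
            ))
    return result


def private_variants(
    a: VariantSet,
    b: VariantSet,
    sample_a: Optional[str] = None,
    sample_b: Optional[str] = None,
) -> tuple[VariantSet, VariantSet]:
    """Alt-carrying records of each set at positions absent from the other."""
    sample_a = _pick_sample(a, sample_a, "A")
    sample_b = _pick_sample(b, sample_b, "B")
    pos_a = {(rec.chrom, rec.pos) for rec in a.records}
    pos_b = {(rec.chrom, rec.pos) for rec in b.records}

    def select(vs: VariantSet, sample: str, other: set) -> VariantSet:
        records = [
            rec for rec in vs.records
            if (rec.chrom, rec.pos) not in other
            and rec.calls[sample].carries_alt
        ]
        return VariantSet(meta=list(vs.meta), samples=list(vs.samples),
                          records=records)

    return select(a, sample_a, pos_b), select(b, sample_b, pos_a)
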