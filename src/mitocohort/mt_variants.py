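"""mtDNA sample QC, variant filtering, heteroplasmy classification and
population-frequency aggregation.

The filtering chain mirrors standard cohort mtDNA practice:

* samples are dropped for nDNA contamination > 2%, a phylogeny-based
  mtDNA contamination flag, or mtDNA copy number < 50 (copy number =
  2 x mean mtDNA depth / mean autosomal depth);
* per-sample calls are kept only when FILTER is PASS, depth exceeds
  100x, the site is not a known WGS artifact / low-complexity position,
  and VAF = AD/DP >= 0.1;
* retained calls are binned into homoplasmic (VAF >= 0.95) and
  heteroplasmic (0.10 <= VAF < 0.95) levels, then aggregated across
  samples into distinct variants with population-frequency categories:
  common (F >= 1%), rare (0.1% <= F < 1%), ultra-rare (F < 0.1%) and
  private (a single carrier).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from mitocohort.circular import MT_GENOME_LENGTH
from mitocohort.io_formats import ARTIFACT_POSITIONS, VcfRecordLite
from mitocohort.rcrs import Region, build_region_table

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class SampleQc:
    """Precomputed per-sample QC metrics (contamination values come from
    upstream nDNA- and phylogeny-based tools and are consumed as-is)."""

    sample_id: str
    mean_mt_depth: float
    mean_autosomal_depth: float
    contamination_fraction: float
    mt_contaminated_flag: bool
    median_insert_size: float

    def __post_init__(self):
        if self.mean_mt_depth <= 0 or self.mean_autosomal_depth <= 0:
            raise ValueError(f"{self.sample_id}: depths must be positive")
        if not 0 <= self.contamination_fraction <= 1:
            raise ValueError(f"{self.sample_id}: contamination outside [0,1]")


@dataclass(frozen=True)
class MtVariantCall:
    sample_id: str
    pos: int
    ref: str
    alt: str
    vaf: float
    dp: int
    level: str  # "homoplasmic" | "heteroplasmic"


@dataclass(frozen=True)
class MtVariantSummary:
    """One distinct variant aggregated across the retained cohort."""

    pos: int
    ref: str
    alt: str
    vtype: str                 # SNV | insertion | deletion
    n_carriers: int
    pop_freq: float
    level_category: str        # homoplasmic_only | heteroplasmic_only | both
    max_het_level: float | None
    region: str | None = None
    singleton: bool = False


def compute_vaf(ad: int, dp: int) -> float:
    """Variant allele fraction: alt-supporting reads over total depth."""
    if dp <= 0:
        raise ValueError("DP must be positive")
    if not 0 <= ad <= dp:
        raise ValueError(f"AD {ad} outside [0, DP={dp}]")
    return ad / dp


def compute_mt_copy_number(mean_mt_depth: float, mean_autosomal_depth: float) -> float:
    """mtDNA copies per cell: 2 x (mean mtDNA depth / mean autosomal depth)."""
    if mean_mt_depth <= 0 or mean_autosomal_depth <= 0:
        raise ValueError("depths must be positive")
    return mean_mt_depth / mean_autosomal_depth * 2.0


def filter_samples(
    qcs: Sequence[SampleQc],
    max_contamination: float = 0.02,
    min_copy_number: float = 50.0,
    min_insert_size: float = 250.0,
    for_numt: bool = False,
) -> tuple[list[SampleQc], list[tuple[SampleQc, str]]]:
    """Split samples into (kept, dropped-with-reason).

    Variant mode drops on contamination strictly above 2%, the
    phylogeny-based contamination flag, or copy number strictly below
    50. NUMT mode drops only on median insert size strictly below
    250 bp (an insert size of exactly 250 is kept).
    """
    if not qcs:
        raise ValueError("no samples supplied")
    kept: list[SampleQc] = []
    dropped: list[tuple[SampleQc, str]] = []
    for qc in qcs:
        if for_numt:
            if qc.median_insert_size < min_insert_size:
                dropped.append((qc, "insert_size"))
            else:
                kept.append(qc)
            continue
        if qc.contamination_fraction > max_contamination:
            dropped.append((qc, "contamination"))
        elif qc.mt_contaminated_flag:
            dropped.append((qc, "mt_contamination"))
        elif compute_mt_copy_number(qc.mean_mt_depth, qc.mean_autosomal_depth) < min_copy_number:
            dropped.append((qc, "copy_number"))
        else:
            kept.append(qc)
    return kept, dropped


def filter_variant_calls(
    records: Iterable[VcfRecordLite],
    sample_id: str,
    min_dp: int = 100,
    min_vaf: float = 0.1,
    artifact_positions: Iterable[int] = ARTIFACT_POSITIONS,
) -> list[MtVariantCall]:
    """Apply the per-call high-quality filter chain.

    Keeps records with FILTER=PASS, DP strictly greater than ``min_dp``
    (a call at exactly 100x is dropped), position outside the artifact
    set, and VAF >= ``min_vaf``; attaches the heteroplasmy level.
    """
    artifact = frozenset(artifact_positions)
    out: list[MtVariantCall] = []
    for rec in records:
        if not rec.passed:
            continue
        if rec.dp <= min_dp:
            continue
        if rec.pos in artifact or rec.is_artifact_site:
            continue
        vaf = compute_vaf(rec.ad, rec.dp)
        if vaf < min_vaf:
            continue
        out.append(
            MtVariantCall(
                sample_id=sample_id,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alt,
                vaf=vaf,
                dp=rec.dp,
                level=classify_heteroplasmy(vaf),
            )
        )
    return out


def classify_heteroplasmy(vaf: float) -> str:
    """Bin a retained VAF: >= 0.95 homoplasmic, [0.10, 0.95) heteroplasmic."""
    if vaf < 0.1:
        raise ValueError(f"VAF {vaf} below 0.1 should have been filtered out")
    if vaf > 1.0:
        raise ValueError(f"VAF {vaf} above 1")
    return "homoplasmic" if vaf >= 0.95 else "heteroplasmic"


def classify_variant_type(ref: str, alt: str) -> tuple[str, str | None]:
    """Classify an allele pair into SNV/insertion/deletion.

    SNVs get a subclass ``transition`` or ``transversion`` plus the
    substitution written on both strands, e.g. ``G>A(H)/C>T(L)``: VCF
    alleles sit on the reference (light, L) strand under the rCRS
    convention, so the heavy-strand class is the complement pair.
    Indels get a subclass like ``del_6bp`` / ``ins_1bp``.
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise ValueError("empty allele")
    if ref == alt:
        raise ValueError("ref == alt")
    for a in (ref, alt):
        if any(c not in "ACGT" for c in a):
            raise ValueError(f"non-ACGT characters in allele {a!r}")
    if len(ref) == 1 and len(alt) == 1:
        kind = "transition" if (ref, alt) in _TRANSITIONS else "transversion"
        h = f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"
        sub = f"{kind};L:{ref}>{alt};H:{h}"
        return "SNV", sub
    if len(ref) > len(alt):
        return "deletion", f"del_{len(ref) - len(alt)}bp"
    return "insertion", f"ins_{len(alt) - len(ref)}bp"


def aggregate_variants(
    calls: Iterable[MtVariantCall],
    n_samples: int,
    region_table: Sequence[Region] | None = None,
) -> list[MtVariantSummary]:
    """Collapse per-sample calls into one summary per distinct variant.

    ``level_category`` comes from the set of per-sample levels;
    ``pop_freq`` is carriers over the retained cohort size;
    ``max_het_level`` is the highest VAF among heteroplasmic carriers
    (None when the variant is homoplasmic-only).
    """
    by_var: dict[tuple[int, str, str], list[MtVariantCall]] = defaultdict(list)
    for c in calls:
        by_var[(c.pos, c.ref, c.alt)].append(c)
    if region_table is None and by_var:
        region_table = build_region_table()
    out: list[MtVariantSummary] = []
    for (pos, ref, alt), carriers in sorted(by_var.items()):
        n_carriers = len({c.sample_id for c in carriers})
        if n_carriers > n_samples:
            raise ValueError(
                f"variant {pos}{ref}>{alt}: {n_carriers} carriers exceed cohort size {n_samples}"
            )
        levels = {c.level for c in carriers}
        if levels == {"homoplasmic"}:
            cat = "homoplasmic_only"
        elif levels == {"heteroplasmic"}:
            cat = "heteroplasmic_only"
        else:
            cat = "both"
        het_vafs = [c.vaf for c in carriers if c.level == "heteroplasmic"]
        region = None
        if region_table is not None and 1 <= pos <= region_table[-1].end:
            region = annotate_region(pos, region_table)[0]
        vtype, _ = classify_variant_type(ref, alt)
        out.append(
            MtVariantSummary(
                pos=pos,
                ref=ref,
                alt=alt,
                vtype=vtype,
                n_carriers=n_carriers,
                pop_freq=n_carriers / n_samples,
                level_category=cat,
                max_het_level=max(het_vafs) if het_vafs else None,
                region=region,
                singleton=n_carriers == 1,
            )
        )
    return out


def frequency_category(n_carriers: int, n_samples: int) -> str:
    """Population-frequency bin: private (one carrier, checked first),
    common (F >= 1%), rare (0.1% <= F < 1%), ultra-rare (F < 0.1%)."""
    if n_carriers < 1:
        raise ValueError("zero carriers has no frequency category")
    if n_carriers > n_samples:
        raise ValueError("carriers exceed cohort size")
    if n_carriers == 1:
        return "private"
    f = Fraction(n_carriers, n_samples)  # exact bin arithmetic at boundaries
    if f >= Fraction(1, 100):
        return "common"
    if f >= Fraction(1, 1000):
        return "rare"
    return "ultra_rare"


def annotate_region(pos: int, region_table: Sequence[Region]) -> tuple[str, str]:
    """Map a 1-based mtDNA position to its (region name, region class)."""
    lo, hi = 1, region_table[-1].end
    if not lo <= pos <= hi:
        raise ValueError(f"position {pos} outside 1..{hi}")
    # region_table is sorted and tiles the genome; binary scan is overkill
    for region in region_table:
        if region.start <= pos <= region.end:
            return region.name, region.region_class
    raise ValueError(f"position {pos} not covered by region table")


def region_enrichment(
    observed_counts_by_region: dict[str, int],
    background_lengths: dict[str, int],
    genome_len: int = MT_GENOME_LENGTH,
) -> dict[str, float]:
    """One-tailed (upper) hypergeometric enrichment p per region.

    Models drawing the total number of observed variant positions from
    the ``genome_len`` background without replacement; for each region
    of length K, p = P(X >= observed) with X ~ Hypergeom(N=genome_len,
    K=region length, n=total draws).
    """
    n_draws = sum(observed_counts_by_region.values())
    out: dict[str, float] = {}
    for region, k in observed_counts_by_region.items():
        if region not in background_lengths:
            raise ValueError(f"region {region!r} missing from background lengths")
        length = background_lengths[region]
        if length <= 0:
            raise ValueError(f"region {region!r} has non-positive length")
        if k > length:
            raise ValueError(f"region {region!r}: observed {k} exceeds length {length}")
        out[region] = float(hypergeom.sf(k - 1, genome_len, length, n_draws))
    return out


def classify_mitotip(score: float) -> str:
    """Bin a MitoTIP tRNA pathogenicity score.

    > 16.25 likely_pathogenic; (12.66, 16.25] possibly_pathogenic;
    (8.44, 12.66] possibly_benign; <= 8.44 likely_benign. Scores equal
    to a published boundary go to the lower bin.
    """
    if score > 16.25:
        return "likely_pathogenic"
    if score > 12.66:
        return "possibly_pathogenic"
    if score > 8.44:
        return "possibly_benign"
    return "likely_benign"


def depth_ratio_diagnostic(qcs: Sequence[SampleQc], threshold: float = 0.04) -> list[dict]:
    """Per-sample nDNA:mtDNA depth-ratio report.

    A ratio below 0.04 means a single nuclear (NUMT-derived) copy cannot
    push a spurious mtDNA call above VAF 0.1; the ratio is reported as a
    diagnostic, never used as a variant filter.
    """
    return [
        {
            "sample_id": qc.sample_id,
            "ndna_mtdna_depth_ratio": qc.mean_autosomal_depth / qc.mean_mt_depth,
            "below_threshold": qc.mean_autosomal_depth / qc.mean_mt_depth < threshold,
        }
        for qc in qcs
    ]
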