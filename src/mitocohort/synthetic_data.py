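"""Synthetic cohorts with planted truth for every pipeline stage.

Each generator is reproducible from (config, seed) and returns a
:class:`TruthTable` alongside its outputs; recovery tests compare
pipeline output against the planted truth, never against re-derived
values. Defaults emulate the study conditions of a deep-WGS cohort:
site depth around 3000x on mtDNA, 97.8% of per-sample calls
homoplasmic and 2.2% heteroplasmic, NUMT evidence as discordant pairs
plus junction-exact split reads on a circular 16,569 bp mitochondrial
genome, and genotype matrices with binomial Hardy-Weinberg structure
and an optional two-population allele-frequency shift driving PC1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mitocohort.circular import MT_GENOME_LENGTH, arc_positions, wrap_position
from mitocohort.io_formats import (
    ARTIFACT_POSITIONS,
    AlignmentRecordLite,
    BedInterval,
)

_BASES = "ACGT"


@dataclass
class TruthTable:
    """Planted ground truth written alongside every generator output."""

    rng_seed: int
    mt_variants: pd.DataFrame | None = None      # pos, ref, alt, sample, true_vaf, level
    numts: pd.DataFrame | None = None            # chrom, junction, arc, carriers, support
    assoc_betas: dict[str, float] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def _ref_base(pos: int) -> str:
    # deterministic synthetic reference base per position
    return _BASES[pos % 4]


def _alt_base(pos: int, rng: np.random.Generator) -> str:
    choices = [b for b in _BASES if b != _ref_base(pos)]
    return choices[rng.integers(len(choices))]


_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chrM,length=16569>
##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=base_qual,Description="Low base quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def gen_mt_cohort(
    n_samples: int = 50,
    depth_mean: float = 3000.0,
    het_rate: float = 0.022,
    hom_rate: float = 0.978,
    artifact_noise_rate: float = 0.05,
    variants_per_sample: float = 36.0,
    n_sites: int = 120,
    het_vaf_range: tuple[float, float] = (0.15, 0.90),
    hom_vaf_range: tuple[float, float] = (0.97, 1.0),
    noiseless: bool = False,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[str]], TruthTable]:
    """Per-sample mtDNA VCFs with planted homo-/heteroplasmic variants.

    A pool of ``n_sites`` distinct sites (outside the artifact set)
    carries cohort-wide allele frequencies; each sample draws about
    ``variants_per_sample`` carried sites. Each call is homoplasmic
    with probability ``hom_rate`` (true VAF in ``hom_vaf_range``) or
    heteroplasmic (true VAF in ``het_vaf_range``); AD is binomial at
    the site depth, or exactly ``round(vaf * dp)`` when ``noiseless``.
    Filter-exercising noise is injected per sample at rate
    ``artifact_noise_rate``: calls at artifact positions, calls with
    VAF < 0.1, sub-100x calls and non-PASS calls, none of which may
    survive the high-quality filter chain.

    Returns ``(vcf_lines_by_sample, truth)``; when ``out_dir`` is given
    the VCFs are also written as ``<sample>.vcf``.
    """
    if not 0 <= het_rate <= 1 and 0 <= hom_rate <= 1:
        raise ValueError("rates must lie in [0,1]")
    rng = np.random.default_rng(seed)
    usable = sorted(set(range(100, MT_GENOME_LENGTH, 130)) - set(ARTIFACT_POSITIONS))
    sites = sorted(rng.choice(usable, size=min(n_sites, len(usable)), replace=False).tolist())
    alts = {pos: _alt_base(pos, rng) for pos in sites}
    # cohort allele frequencies sized so that E[carried sites] matches
    site_freq = rng.dirichlet(np.ones(len(sites))) * variants_per_sample
    site_freq = np.clip(site_freq, 0.005, 0.98)

    truth_rows = []
    vcfs: dict[str, list[str]] = {}
    p_het = het_rate / (het_rate + hom_rate)
    for i in range(n_samples):
        sample = f"S{i:04d}"
        lines = [_VCF_HEADER.format(sample=sample)]
        carried = [pos for pos, f in zip(sites, site_freq) if rng.random() < f]
        records = []
        for pos in carried:
            is_het = rng.random() < p_het
            lo, hi = het_vaf_range if is_het else hom_vaf_range
            vaf = float(rng.uniform(lo, hi))
            dp = max(int(rng.normal(depth_mean, depth_mean * 0.1)), 150)
            ad = int(round(vaf * dp)) if noiseless else int(rng.binomial(dp, vaf))
            records.append((pos, _ref_base(pos), alts[pos], "PASS", ad, dp))
            truth_rows.append(
                {
                    "sample_id": sample,
                    "pos": pos,
                    "ref": _ref_base(pos),
                    "alt": alts[pos],
                    "true_vaf": vaf,
                    "level": "heteroplasmic" if is_het else "homoplasmic",
                }
            )
        # spurious calls exercising each filter; never in truth
        n_noise = rng.binomial(20, artifact_noise_rate)
        art_pool = sorted(ARTIFACT_POSITIONS)
        for _ in range(n_noise):
            kind = rng.integers(4)
            dp = max(int(rng.normal(depth_mean, depth_mean * 0.1)), 150)
            if kind == 0:  # artifact site, otherwise clean
                pos = int(art_pool[rng.integers(len(art_pool))])
                ad = int(rng.binomial(dp, 0.5))
                filt = "PASS"
            elif kind == 1:  # sub-threshold VAF
                pos = int(rng.choice(usable))
                ad = int(rng.binomial(dp, 0.04))
                filt = "PASS"
            elif kind == 2:  # shallow site (DP <= 100)
                pos = int(rng.choice(usable))
                dp = int(rng.integers(20, 101))
                ad = int(rng.binomial(dp, 0.5))
                filt = "PASS"
            else:  # caller-failed record
                pos = int(rng.choice(usable))
                ad = int(rng.binomial(dp, 0.5))
                filt = "base_qual"
            ad = min(ad, dp)
            if ad == 0:
                continue
            records.append((pos, _ref_base(pos), _alt_base(pos, rng), filt, ad, dp))
        for pos, ref, alt, filt, ad, dp in sorted(records):
            gt = "1/1" if ad / dp >= 0.95 else "0/1"
            lines.append(
                f"chrM\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.\tGT:AD:DP\t"
                f"{gt}:{dp - ad},{ad}:{dp}\n"
            )
        vcfs[sample] = lines
    truth = TruthTable(rng_seed=seed, mt_variants=pd.DataFrame(truth_rows))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample, lines in vcfs.items():
            (out_dir / f"{sample}.vcf").write_text("".join(lines))
        truth.mt_variants.to_csv(out_dir / "truth_mt_variants.tsv", sep="\t", index=False)
    return vcfs, truth


def gen_numt_reads(
    n_samples: int = 20,
    nuclear_len: int = 5_000_000,
    nuclear_chrom: str = "chr1",
    n_insertions: int = 10,
    n_decoys: int = 0,
    support_pairs: tuple[int, int] = (5, 12),
    decoy_pairs: tuple[int, int] = (1, 4),
    n_split_reads: int = 3,
    insert_size: int = 500,
    read_len: int = 150,
    arc_size_range: tuple[int, int] = (50, 2000),
    carriers_per_insertion: tuple[int, int] = (1, 4),
    n_background: int = 200,
    seed: int = 0,
) -> tuple[list[AlignmentRecordLite], TruthTable]:
    """Alignment evidence around planted NUMT insertions.

    Each planted insertion at nuclear junction J with mtDNA arc
    [a, a+size) emits, per carrier, ``support_pairs`` discordant pairs
    (nuclear mate within the insert-size window left of J, chrM mate on
    the arc) and ``n_split_reads`` junction-exact split reads per side:
    the left junction joins nuclear J to arc start a, the right
    junction joins nuclear J+1 to arc end b. Decoys are planted
    identically but with ``decoy_pairs`` (sub-threshold) support.
    Background noise comprises concordant nuclear pairs, nuclear-
    nuclear discordant pairs and chrM-internal pairs, all of which the
    detector must ignore.
    """
    if insert_size < 2 * read_len:
        raise ValueError("insert_size must be at least twice read_len")
    if arc_size_range[0] < 5:
        raise ValueError("minimum arc size is 5 bp")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]

    n_total = n_insertions + n_decoys
    # junctions mutually separated so grouping never merges distinct truths
    min_sep = 5_000
    junctions: list[int] = []
    while len(junctions) < n_total:
        j = int(rng.integers(insert_size + 10, nuclear_len - insert_size - 10))
        if all(abs(j - k) >= min_sep for k in junctions):
            junctions.append(j)

    records: list[AlignmentRecordLite] = []
    truth_rows = []
    rid = 0

    def emit_insertion(j: int, is_decoy: bool, idx: int):
        nonlocal rid
        size = int(np.exp(rng.uniform(np.log(arc_size_range[0]), np.log(arc_size_range[1]))))
        a = int(rng.integers(1, MT_GENOME_LENGTH + 1))
        b = wrap_position(a + size)
        n_carr = int(rng.integers(carriers_per_insertion[0], carriers_per_insertion[1] + 1))
        carrier_set = list(rng.choice(samples, size=min(n_carr, n_samples), replace=False))
        pair_lo, pair_hi = decoy_pairs if is_decoy else support_pairs
        arc = arc_positions(a, b)
        for sample in carrier_set:
            n_pairs = int(rng.integers(pair_lo, pair_hi + 1))
            for _ in range(n_pairs):
                npos = int(rng.integers(j - insert_size + 1, j - read_len + 1))
                mpos = int(arc[rng.integers(len(arc))])
                records.append(
                    AlignmentRecordLite(
                        read_id=f"r{rid}", sample_id=sample, chrom=nuclear_chrom,
                        pos=npos, strand="+", mate_chrom="chrM", mate_pos=mpos,
                        is_split=False, cigar_or_segments=f"{read_len}M", mapq=60,
                    )
                )
                rid += 1
            if is_decoy:
                n_sr = min(n_split_reads, 1)  # decoys may carry a stray split read
            else:
                n_sr = n_split_reads
            for _ in range(n_sr):
                # left junction: nuclear segment ends at j, mito starts at a.
                # Only the junction-facing endpoints matter downstream; the far
                # mito end is clamped rather than wrapped for short arcs near
                # the origin.
                a_far = min(a + read_len // 2 - 1, MT_GENOME_LENGTH)
                seg = f"{nuclear_chrom}:{j - read_len // 2 + 1}-{j};chrM:{a}-{a_far}"
                records.append(
                    AlignmentRecordLite(
                        read_id=f"r{rid}", sample_id=sample, chrom=nuclear_chrom,
                        pos=j - read_len // 2 + 1, strand="+", mate_chrom=nuclear_chrom,
                        mate_pos=j, is_split=True, cigar_or_segments=seg, mapq=60,
                    )
                )
                rid += 1
                # right junction: mito segment ends at b, nuclear resumes at j+1
                b_far = max(b - read_len // 2 + 1, 1)
                seg = f"chrM:{b_far}-{b};{nuclear_chrom}:{j + 1}-{j + read_len // 2}"
                records.append(
                    AlignmentRecordLite(
                        read_id=f"r{rid}", sample_id=sample, chrom=nuclear_chrom,
                        pos=j + 1, strand="+", mate_chrom=nuclear_chrom,
                        mate_pos=j + 1, is_split=True, cigar_or_segments=seg, mapq=60,
                    )
                )
                rid += 1
        truth_rows.append(
            {
                "numt_id": ("decoy" if is_decoy else "numt") + f"_{idx}",
                "nuclear_chrom": nuclear_chrom,
                "nuclear_bp_left": j,
                "nuclear_bp_right": j + 1,
                "mito_bp_a": a,
                "mito_bp_b": b,
                "size_bp": size,
                "carriers": ",".join(sorted(carrier_set)),
                "n_carriers": len(carrier_set),
                "is_decoy": is_decoy,
            }
        )

    for idx, j in enumerate(junctions[:n_insertions]):
        emit_insertion(j, is_decoy=False, idx=idx)
    for idx, j in enumerate(junctions[n_insertions:]):
        emit_insertion(j, is_decoy=True, idx=idx)

    # background noise: none of it involves exactly-one-chrM-mate pairs
    for _ in range(n_background):
        sample = samples[rng.integers(n_samples)]
        kind = rng.integers(3)
        if kind == 0:  # concordant nuclear pair
            p = int(rng.integers(1, nuclear_len - 1000))
            rec = AlignmentRecordLite(
                read_id=f"r{rid}", sample_id=sample, chrom=nuclear_chrom, pos=p,
                strand="+", mate_chrom=nuclear_chrom, mate_pos=p + insert_size,
                is_split=False, cigar_or_segments=f"{read_len}M", mapq=60,
            )
        elif kind == 1:  # inter-chromosomal nuclear discordant
            rec = AlignmentRecordLite(
                read_id=f"r{rid}", sample_id=sample, chrom=nuclear_chrom,
                pos=int(rng.integers(1, nuclear_len)), strand="-",
                mate_chrom="chr2", mate_pos=int(rng.integers(1, nuclear_len)),
                is_split=False, cigar_or_segments=f"{read_len}M", mapq=60,
            )
        else:  # chrM-internal pair
            rec = AlignmentRecordLite(
                read_id=f"r{rid}", sample_id=sample, chrom="chrM",
                pos=int(rng.integers(1, MT_GENOME_LENGTH - 1000)), strand="+",
                mate_chrom="chrM", mate_pos=int(rng.integers(1, MT_GENOME_LENGTH)),
                is_split=False, cigar_or_segments=f"{read_len}M", mapq=60,
            )
        records.append(rec)
        rid += 1

    truth = TruthTable(
        rng_seed=seed,
        numts=pd.DataFrame(truth_rows),
        extras={"samples": samples, "nuclear_len": nuclear_len},
    )
    return records, truth


def gen_assoc_dataset(
    n: int = 2000,
    n_snps: int = 500,
    n_causal: int = 5,
    beta: float = 0.1,
    maf_range: tuple[float, float] = (0.05, 0.5),
    two_populations: bool = False,
    pop_shift: float = 0.2,
    confound: float = 0.0,
    noise_sd: float = 0.05,
    baseline: float = 0.4,
    missing_rate: float = 0.0,
    seed: int = 0,
):
    """Genotype dosages with a planted linear effect on a heteroplasmy-
    like phenotype.

    Genotypes are binomial(2, p) with per-SNP allele frequency in
    ``maf_range``; with ``two_populations`` half the cohort gets
    allele frequencies shifted by ``pop_shift`` on a random subset of
    SNPs, creating PC1 structure, and ``confound`` adds a population
    term to the phenotype. Phenotype = baseline + sum(beta x dosage
    over causal SNPs) + noise, clipped to [0, 1] to mimic a
    heteroplasmic level (defaults keep clipping inactive).
    """
    if n_causal > n_snps:
        raise ValueError("n_causal exceeds n_snps")
    rng = np.random.default_rng(seed)
    from mitocohort.assoc import GenotypeMatrix  # local import to avoid cycle

    freqs = rng.uniform(*maf_range, size=n_snps)
    pop = np.zeros(n, dtype=int)
    if two_populations:
        pop[n // 2 :] = 1
        shifted = rng.random(n_snps) < 0.5
        f0 = freqs.copy()
        f1 = np.clip(freqs + np.where(shifted, pop_shift, 0.0), 0.01, 0.99)
    else:
        f0 = f1 = freqs
    p_mat = np.where(pop[:, None] == 0, f0[None, :], f1[None, :])
    dosages = rng.binomial(2, p_mat).astype(float)
    if missing_rate > 0:
        miss = rng.random(dosages.shape) < missing_rate
        dosages[miss] = np.nan

    causal_idx = rng.choice(n_snps, size=n_causal, replace=False)
    y = np.full(n, baseline)
    for j in causal_idx:
        col = dosages[:, j]
        y = y + beta * np.where(np.isnan(col), np.nanmean(col), col)
    y = y + confound * pop + rng.normal(0, noise_sd, size=n)
    y = np.clip(y, 0.0, 1.0)

    gmat = GenotypeMatrix(
        samples=[f"S{i:05d}" for i in range(n)],
        variant_ids=[f"snp{j}" for j in range(n_snps)],
        dosages=dosages,
    )
    truth = TruthTable(
        rng_seed=seed,
        assoc_betas={f"snp{j}": beta for j in causal_idx},
        extras={"pop": pop, "causal_idx": causal_idx.tolist()},
    )
    return gmat, y, truth


def gen_annotation_tracks(
    chrom_sizes: dict[str, int],
    track_specs: dict[str, float],
    n_intervals_per_chrom: int = 50,
    seed: int = 0,
) -> dict[str, list[BedInterval]]:
    """Random non-overlapping BED tracks at requested coverage fractions.

    For each chromosome, the covered bases are split into equal-length
    intervals placed at random non-overlapping offsets (uniform gap
    composition), so realized coverage matches the request exactly up
    to integer rounding.
    """
    rng = np.random.default_rng(seed)
    tracks: dict[str, list[BedInterval]] = {}
    for name, coverage in track_specs.items():
        if not 0 < coverage <= 1:
            raise ValueError(f"track {name!r}: coverage must be in (0, 1]")
        ivs: list[BedInterval] = []
        for chrom, size in sorted(chrom_sizes.items()):
            covered = int(round(coverage * size))
            if covered == 0:
                continue
            k = min(n_intervals_per_chrom, covered)
            lens = np.full(k, covered // k)
            lens[: covered % k] += 1
            free = size - covered
            gaps = rng.multinomial(free, np.ones(k + 1) / (k + 1))
            pos = 0
            for g, ln in zip(gaps[:-1], lens):
                pos += int(g)
                ivs.append(BedInterval(chrom=chrom, start=pos, end=pos + int(ln), name=name))
                pos += int(ln)
        tracks[name] = ivs
    return tracks
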