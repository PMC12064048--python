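"""Construction of mutational-context-matched neutral control SNP sets.

Selected SNPs (nonsynonymous or synonymous) are paired with short-intron
SNPs sharing the same mutational context: the two flanking reference bases
plus the unordered ref/alt allele pair (C/T and T/C are one context since
all downstream analysis is folded; reverse complements are NOT merged).
There are 6 unordered allele pairs x 16 flank combinations = 96 contexts.
Each selected SNP takes the nearest same-chromosome, same-context intron
SNP not already used; pairing is without replacement.  Paired sites are
then projected (expected hypergeometric downsampling) to a uniform sample
size and emitted as folded spectra, so the selected and neutral site
totals are equal by construction and lambda_hat = rho_hat downstream.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .sfs_core import SFS, fold

logger = logging.getLogger(__name__)

__all__ = [
    "SiteRecord",
    "MutationContext",
    "context_of",
    "annotate_contexts",
    "pair_nearest",
    "build_paired_sfs",
    "load_vcf",
    "SiteClassifier",
    "all_contexts",
]

_BASES = "ACGT"
SITE_CLASSES = ("nonsynonymous", "synonymous", "short_intron")


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP with its site class and sample allele counts."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    site_class: str
    derived_count: int
    genotyped_n: int

    def __post_init__(self):
        if self.ref == self.alt or len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not a biallelic SNP: {self.ref}/{self.alt}")
        if not 0 <= self.derived_count <= self.genotyped_n:
            raise ValueError(
                f"allele count {self.derived_count} outside [0, {self.genotyped_n}]"
            )


@dataclass(frozen=True)
class MutationContext:
    """Flanking bases plus the unordered allele pair (lexicographic)."""

    left_base: str
    right_base: str
    allele_pair: tuple

    def __str__(self):
        a, b = self.allele_pair
        return f"{self.left_base}{a}/{b}{self.right_base}"


def all_contexts():
    """Enumerate the 96 possible mutational contexts."""
    pairs = list(combinations(_BASES, 2))  # 6 unordered
    return [
        MutationContext(lft, rgt, pair)
        for lft, rgt in product(_BASES, repeat=2)
        for pair in pairs
    ]


def context_of(site: SiteRecord, reference) -> MutationContext:
    """Mutational context of a SNP from the reference sequence.

    ``reference`` maps chromosome name to sequence (a dict of strings or a
    pyfaidx.Fasta work alike).  Raises on an ambiguous (non-ACGT) flank;
    callers that want skip-and-log behaviour use :func:`annotate_contexts`.
    """
    seq = reference[site.chrom]
    left = str(seq[site.pos - 2]).upper()
    right = str(seq[site.pos]).upper()
    if left not in _BASES or right not in _BASES:
        raise ValueError(
            f"{site.chrom}:{site.pos}: ambiguous flanking base {left!r}/{right!r}"
        )
    pair = tuple(sorted((site.ref.upper(), site.alt.upper())))
    return MutationContext(left, right, pair)


def annotate_contexts(sites, reference) -> dict:
    """Map each site to its context, skipping (and logging) ambiguous flanks."""
    out = {}
    skipped = 0
    for s in sites:
        try:
            out[s] = context_of(s, reference)
        except (ValueError, KeyError, IndexError) as exc:
            skipped += 1
            logger.info("skipping %s:%d (%s)", s.chrom, s.pos, exc)
    if skipped:
        logger.warning("%d site(s) skipped for ambiguous or missing flanks", skipped)
    return out


def pair_nearest(selected, introns, reference):
    """Greedily pair each selected SNP with its nearest unused same-context
    short-intron SNP on the same chromosome.

    Selected sites are visited in genomic order (chromosome, position);
    equidistant candidates break ties toward the lower coordinate.
    Selected sites with no available match are dropped and counted.
    Returns (list of (selected, intron) pairs, number dropped).
    """
    sel_ctx = annotate_contexts(selected, reference)
    int_ctx = annotate_contexts(introns, reference)
    if not int_ctx:
        logger.warning("no usable intron SNPs: empty pairing")
        return [], len(selected)

    # (chrom, context) -> sorted positions and records, with used flags
    pools = {}
    for s, c in int_ctx.items():
        pools.setdefault((s.chrom, c), []).append(s)
    for key in pools:
        pools[key].sort(key=lambda s: s.pos)
    positions = {key: [s.pos for s in recs] for key, recs in pools.items()}
    used = {key: [False] * len(recs) for key, recs in pools.items()}

    pairs = []
    dropped = 0
    for s in sorted(sel_ctx, key=lambda s: (s.chrom, s.pos)):
        key = (s.chrom, sel_ctx[s])
        if key not in pools:
            dropped += 1
            continue
        pos_list = positions[key]
        flags = used[key]
        j = bisect.bisect_left(pos_list, s.pos)
        lo, hi = j - 1, j
        while lo >= 0 and flags[lo]:
            lo -= 1
        while hi < len(pos_list) and flags[hi]:
            hi += 1
        cand = []
        if lo >= 0:
            cand.append((abs(pos_list[lo] - s.pos), pos_list[lo], lo))
        if hi < len(pos_list):
            cand.append((abs(pos_list[hi] - s.pos), pos_list[hi], hi))
        best = min(cand)[2] if cand else None  # distance, then lower coordinate
        if best is None:
            dropped += 1
            continue
        flags[best] = True
        pairs.append((s, pools[key][best]))
    if dropped:
        logger.warning("%d selected site(s) had no available context match", dropped)
    return pairs, dropped


def _site_spectrum_contribution(site: SiteRecord, target_n: int) -> np.ndarray:
    """Expected unfolded allele-count distribution after downsampling the
    site from genotyped_n to target_n chromosomes (monomorphic classes
    discarded)."""
    j = np.arange(1, target_n)
    return hypergeom.pmf(j, site.genotyped_n, site.derived_count, target_n)


def build_paired_sfs(pairs, target_n: int):
    """Folded (selected SFS, neutral SFS) from matched SNP pairs.

    Each site contributes its expected hypergeometric projection from its
    own genotyped_n down to ``target_n``.  A pair is dropped whole if either
    member was genotyped on fewer than ``target_n`` chromosomes, preserving
    the equal-totals property of the paired design.
    """
    if target_n < 2:
        raise ValueError("target_n must be >= 2")
    sel_counts = np.zeros(target_n - 1)
    neu_counts = np.zeros(target_n - 1)
    dropped = 0
    kept = 0
    for s, m in pairs:
        if s.genotyped_n < target_n or m.genotyped_n < target_n:
            dropped += 1
            logger.info(
                "dropping pair %s:%d / %s:%d (genotyped below %d)",
                s.chrom,
                s.pos,
                m.chrom,
                m.pos,
                target_n,
            )
            continue
        sel_counts += _site_spectrum_contribution(s, target_n)
        neu_counts += _site_spectrum_contribution(m, target_n)
        kept += 1
    if dropped:
        logger.warning("%d pair(s) dropped for insufficient sample size", dropped)
    selected = fold(SFS(target_n, sel_counts, folded=False, label="selected"))
    neutral = fold(SFS(target_n, neu_counts, folded=False, label="neutral (short intron)"))
    return selected, neutral


class SiteClassifier:
    """Assigns a site class by per-site table or interval lists.

    ``from_tsv`` reads chrom<TAB>pos<TAB>class (1-based positions);
    ``from_bed`` attaches one class per BED file (0-based half-open).
    """

    def __init__(self):
        self._by_pos = {}
        self._trees = {}

    @classmethod
    def from_tsv(cls, path) -> "SiteClassifier":
        self = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 3:
                    raise ValueError(f"{path}, line {lineno}: need chrom pos class")
                chrom, pos, cls_name = fields[0], int(fields[1]), fields[2]
                self._by_pos[(chrom, pos)] = cls_name
        return self

    @classmethod
    def from_bed(cls, paths_by_class: dict) -> "SiteClassifier":
        self = cls()
        for cls_name, path in paths_by_class.items():
            with open(path) as fh:
                for line in fh:
                    if not line.strip() or line.startswith(("#", "track")):
                        continue
                    chrom, start, end = line.split()[:3]
                    tree = self._trees.setdefault(chrom, IntervalTree())
                    tree[int(start) : int(end)] = cls_name
        return self

    def __call__(self, chrom: str, pos: int):
        hit = self._by_pos.get((chrom, pos))
        if hit is not None:
            return hit
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = tree[pos - 1]  # BED is 0-based half-open
        return next(iter(hits)).data if hits else None


def load_vcf(path, class_map, min_call_fraction: float = 0.5):
    """Read biallelic SNPs from a VCF v4 file into SiteRecords.

    ``class_map`` is a :class:`SiteClassifier` (or any callable
    (chrom, pos) -> class or None); unclassified sites are dropped.
    Multi-allelic records, non-SNPs and sites genotyped on fewer than
    ``min_call_fraction`` of individuals are dropped with counts logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    records = []
    n_multi = n_lowcall = n_unclassified = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_multi += 1
            continue
        if v.call_rate < min_call_fraction:
            n_lowcall += 1
            continue
        cls_name = class_map(v.CHROM, v.POS)
        if cls_name is None:
            n_unclassified += 1
            continue
        alleles = [a for g in v.genotypes for a in g[:-1] if a >= 0]
        records.append(
            SiteRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                site_class=cls_name,
                derived_count=sum(1 for a in alleles if a == 1),
                genotyped_n=len(alleles),
            )
        )
    logger.info(
        "load_vcf: kept %d sites; dropped %d multi-allelic/non-SNP, "
        "%d low call rate, %d unclassified",
        len(records),
        n_multi,
        n_lowcall,
        n_unclassified,
    )
    return records
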