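import itertools

import numpy as np
import pytest

from sfratios.neutral_control import (
    SiteClassifier,
    SiteRecord,
    all_contexts,
    annotate_contexts,
    build_paired_sfs,
    context_of,
    load_vcf,
    pair_nearest,
)
from sfratios.sfs_core import make_ratios


def site(pos, ref="C", alt="T", cls="nonsynonymous", d=1, g=20, chrom="2L"):
    return SiteRecord(chrom, pos, ref, alt, cls, d, g)


class TestMutationContext:
    def test_allele_order_is_irrelevant(self):
        ref = {"2L": "AACAA"}  # SNP at pos 3, flanks A_A
        a = context_of(site(3, "C", "T"), ref)
        b = context_of(site(3, "T", "C"), {"2L": "AATAA"})
        assert a == b

    def test_exactly_96_contexts_reachable(self):
        contexts = set()
        for left, right, ref, alt in itertools.product("ACGT", repeat=4):
            if ref == alt:
                continue
            reference = {"2L": f"X{left}{ref}{right}X"}
            contexts.add(context_of(site(3, ref, alt), reference))
        assert len(contexts) == 96
        assert contexts == set(all_contexts())

    def test_ambiguous_flank_raises_and_is_skipped(self):
        ref = {"2L": "ANCAA"}
        with pytest.raises(ValueError, match="ambiguous"):
            context_of(site(3), ref)
        assert annotate_contexts([site(3)], ref) == {}

    def test_invalid_snp_rejected(self):
        with pytest.raises(ValueError):
            SiteRecord("2L", 5, "C", "C", "synonymous", 1, 10)
        with pytest.raises(ValueError):
            SiteRecord("2L", 5, "C", "T", "synonymous", 11, 10)


class TestPairNearest:
    def _ref(self, length=1000):
        # constant-A reference: every C/T SNP shares the A_A context
        return {"2L": "A" * length}

    def test_nearest_wins(self):
        sel = [site(500)]
        introns = [site(600, cls="short_intron"), site(990, cls="short_intron")]
        pairs, dropped = pair_nearest(sel, introns, self._ref())
        assert dropped == 0 and pairs[0][1].pos == 600

    def test_without_replacement(self):
        sel = [site(500), site(510)]
        introns = [site(505, cls="short_intron")]
        pairs, dropped = pair_nearest(sel, introns, self._ref())
        assert len(pairs) == 1 and dropped == 1
        assert pairs[0][0].pos == 500  # genomic order decides priority

    def test_equidistant_tie_breaks_low_coordinate(self):
        sel = [site(500)]
        introns = [site(490, cls="short_intron"), site(510, cls="short_intron")]
        pairs, _ = pair_nearest(sel, introns, self._ref())
        assert pairs[0][1].pos == 490

    def test_context_mismatch_blocks_pairing(self):
        sel = [site(500, "C", "G")]
        introns = [site(520, "C", "T", cls="short_intron")]
        pairs, dropped = pair_nearest(sel, introns, self._ref())
        assert pairs == [] and dropped == 1

    def test_empty_intron_list(self):
        pairs, dropped = pair_nearest([site(500)], [], self._ref())
        assert pairs == [] and dropped == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        ref = self._ref(20000)
        sel = [site(int(p)) for p in np.sort(rng.choice(19000, 10, replace=False) + 10)]
        introns = [
            site(int(p), cls="short_intron")
            for p in np.sort(rng.choice(19000, 10, replace=False) + 10)
        ]
        pairs, _ = pair_nearest(sel, introns, ref)
        # independent re-derivation: same greedy rule, naive O(n^2) scan
        used = set()
        expected = []
        for s in sorted(sel, key=lambda s: (s.chrom, s.pos)):
            cands = [m for m in introns if m.pos not in used]
            if not cands:
                continue
            best = min(cands, key=lambda m: (abs(m.pos - s.pos), m.pos))
            used.add(best.pos)
            expected.append((s.pos, best.pos))
        assert [(s.pos, m.pos) for s, m in pairs] == expected

    def test_matching_is_injective(self):
        rng = np.random.default_rng(12)
        ref = self._ref(50000)
        sel = [site(int(p)) for p in rng.choice(49000, 40, replace=False) + 10]
        introns = [
            site(int(p), cls="short_intron")
            for p in rng.choice(49000, 25, replace=False) + 10
        ]
        pairs, _ = pair_nearest(sel, introns, ref)
        assert len({s.pos for s, _ in pairs}) == len(pairs)
        assert len({m.pos for _, m in pairs}) == len(pairs)


class TestBuildPairedSFS:
    def test_single_site_hypergeometric_enumeration(self):
        # 2 derived of 4, projected to 2 chromosomes: P(1 of 2) = 4/6
        pairs = [
            (site(100, d=2, g=4), site(200, d=2, g=4, cls="short_intron"))
        ]
        sel, neu = build_paired_sfs(pairs, target_n=2)
        assert sel.folded and sel.n == 2
        np.testing.assert_allclose(sel.counts, [4.0 / 6.0])
        np.testing.assert_allclose(neu.counts, [4.0 / 6.0])

    def test_sites_at_target_n_tabulate_and_fold(self):
        pairs = [
            (site(100, d=1, g=4), site(200, d=3, g=4, cls="short_intron")),
            (site(300, d=2, g=4), site(400, d=2, g=4, cls="short_intron")),
        ]
        sel, neu = build_paired_sfs(pairs, target_n=4)
        np.testing.assert_allclose(sel.counts, [1.0, 1.0])
        np.testing.assert_allclose(neu.counts, [1.0, 1.0])  # 3-of-4 folds to 1

    def test_underpowered_pair_dropped_whole(self):
        pairs = [
            (site(100, d=2, g=10), site(200, d=2, g=4, cls="short_intron")),
            (site(300, d=2, g=10), site(400, d=2, g=10, cls="short_intron")),
        ]
        sel, neu = build_paired_sfs(pairs, target_n=8)
        # one pair survives; totals stay equal on both sides
        assert sel.segregating_sites == pytest.approx(neu.segregating_sites)

    def test_mass_conservation_with_projection_loss(self):
        rng = np.random.default_rng(13)
        pairs = []
        for k in range(50):
            d1, d2 = rng.integers(1, 20, 2)
            pairs.append(
                (
                    site(100 + k, d=int(d1), g=20),
                    site(5000 + k, d=int(d2), g=20, cls="short_intron"),
                )
            )
        sel, neu = build_paired_sfs(pairs, target_n=10)
        # per side: retained SFS mass + mass projected to monomorphic = site count
        assert sel.segregating_sites <= 50.0 + 1e-9
        assert neu.segregating_sites <= 50.0 + 1e-9
        assert sel.segregating_sites > 45.0  # little mass lost at these counts


class TestVCFPipeline:
    def test_load_vcf_filters(self, synthetic_vcf):
        classifier = SiteClassifier.from_tsv(synthetic_vcf["classes"])
        records = load_vcf(synthetic_vcf["vcf"], classifier, min_call_fraction=0.5)
        assert len(records) == 1601  # 1600 clean + the 60%-called record
        assert all(r.genotyped_n in (20, 12) for r in records)
        # the tri-allelic and the 40%-called records are absent
        classes = {r.site_class for r in records}
        assert classes == {"nonsynonymous", "short_intron"}

    def test_low_call_threshold(self, synthetic_vcf):
        classifier = SiteClassifier.from_tsv(synthetic_vcf["classes"])
        strict = load_vcf(synthetic_vcf["vcf"], classifier, min_call_fraction=0.7)
        assert len(strict) == 1600

    def test_classifier_from_bed(self, tmp_path):
        bed = tmp_path / "si.bed"
        bed.write_text("2L\t100\t200\tx\n")
        clf = SiteClassifier.from_bed({"short_intron": bed})
        assert clf("2L", 101) == "short_intron"  # first base of the interval
        assert clf("2L", 200) == "short_intron"
        assert clf("2L", 201) is None
        assert clf("3R", 150) is None

    def test_neutral_pipeline_recovers_unit_rho(self, synthetic_vcf, grid100f):
        # selected and intron sites drawn from one neutral generator:
        # the full pipeline should find rho ~ 1
        from pyfaidx import Fasta

        from sfratios.inference import fit
        from sfratios.prf_expectations import get_grid

        classifier = SiteClassifier.from_tsv(synthetic_vcf["classes"])
        records = load_vcf(synthetic_vcf["vcf"], classifier)
        selected = [r for r in records if r.site_class == "nonsynonymous"]
        introns = [r for r in records if r.site_class == "short_intron"]
        reference = Fasta(str(synthetic_vcf["fasta"]))
        pairs, _ = pair_nearest(selected, introns, reference)
        assert len(pairs) > 500
        sel, neu = build_paired_sfs(pairs, target_n=16)
        ratios = make_ratios(sel, neu)
        assert ratios.X == pytest.approx(ratios.Y, rel=0.15)
        res = fit(ratios, "fixed", grid=get_grid(16, True), n_starts=3, seed=0)
        assert res.rho_hat == pytest.approx(1.0, abs=0.2)
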