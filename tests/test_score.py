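"""UVMSE scoring: variant IO, filtering, windows, Eq.-style enrichment."""

import numpy as np
import pytest
from pyfaidx import Fasta

from uvsig.score import (
    ChannelCounts,
    ContextWindow,
    VariantRecord,
    channel_enrichment,
    extract_window,
    filter_variants,
    read_variants,
    score_sample,
    signature_enrichment,
    tally_channel_counts,
    weighted_uv_load,
)
from uvsig.synth import synth_variants, write_vcf
from uvsig.tables import reverse_complement


def write_fasta(path, seqs):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    return path


@pytest.fixture()
def toy_reference(tmp_path):
    seq = "ACGTACGTTCCGAGACGTACGTACGTTCCACGTACGTACG" * 5
    return write_fasta(tmp_path / "toy.fasta", {"chr1": seq})


class TestReadVariants:
    def test_snv_passthrough_and_indel_drop(self, tmp_path, toy_reference):
        seqs = {"chr1": str(Fasta(str(toy_reference))["chr1"][:])}
        vcf = tmp_path / "v.vcf"
        with open(vcf, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n')
            fh.write(f"##contig=<ID=chr1,length={len(seqs['chr1'])}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            fh.write("chr1\t10\t.\tC\tT\t99\tPASS\tDP=200\n")
            fh.write("chr1\t20\t.\tC\tCA\t99\tPASS\tDP=200\n")  # insertion
        recs, log = read_variants(vcf, toy_reference)
        assert len(recs) == 1
        assert log["n_indels_dropped"] == 1
        assert recs[0] == VariantRecord("chr1", 10, "C", "T", 99.0, 200, "v")

    def test_mnv_decomposed_into_component_snvs(self, tmp_path, toy_reference):
        # UV-typical CC>TT tandem at positions 10-11 (sequence ...TCC...)
        vcf = tmp_path / "mnv.vcf"
        with open(vcf, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            fh.write("chr1\t10\t.\tCC\tTT\t80\tPASS\t.\n")
        recs, _ = read_variants(vcf, toy_reference)
        assert [(r.pos, r.ref, r.alt) for r in recs] == [(10, "C", "T"), (11, "C", "T")]

    def test_reference_mismatch_rejected(self, tmp_path, toy_reference):
        vcf = tmp_path / "bad.vcf"
        with open(vcf, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            fh.write("chr1\t10\t.\tA\tT\t80\tPASS\t.\n")  # actual base is C
        recs, log = read_variants(vcf, toy_reference)
        assert recs == [] and log["n_ref_mismatch"] == 1

    def test_maf_input(self, tmp_path, toy_reference):
        maf = tmp_path / "v.maf"
        maf.write_text(
            "Chromosome\tStart_Position\tReference_Allele\tTumor_Seq_Allele2\tTumor_Sample_Barcode\n"
            "chr1\t10\tC\tT\ts1\n"
            "chr1\t15\tG\t-\ts1\n"  # deletion
        )
        recs, log = read_variants(maf, toy_reference)
        assert len(recs) == 1 and recs[0].sample == "s1"
        assert log["n_indels_dropped"] == 1


class TestFilterVariants:
    @pytest.mark.parametrize(
        "qual,depth,kept",
        [(50.0, 100, True), (49.0, 100, False), (50.0, 99, False), (None, None, True)],
    )
    def test_quality_and_depth_boundaries(self, qual, depth, kept):
        rec = VariantRecord("chr1", 10, "C", "T", qual, depth)
        assert (filter_variants([rec]) == [rec]) is kept

    def test_bed_region_restriction(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t9\t12\n")  # 0-based half-open: positions 10-12
        recs = [VariantRecord("chr1", p, "C", "T", 99.0, 200) for p in (9, 10, 12, 13)]
        kept = filter_variants(recs, regions=bed)
        assert [r.pos for r in kept] == [10, 12]

    def test_empty_bed_removes_everything(self, tmp_path):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        assert filter_variants([VariantRecord("chr1", 5, "C", "T")], regions=bed) == []

    def test_malformed_bed_fails(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\tnot_a_number\t5\n")
        with pytest.raises(ValueError, match="malformed"):
            filter_variants([], regions=bed)


class TestExtractWindow:
    def test_interior_window_is_41nt(self, reference_fasta, reference_seqs):
        seq = reference_seqs["contig1"]
        win = extract_window(reference_fasta, VariantRecord("contig1", 100, seq[99], "N" if seq[99] != "N" else "A"))
        assert len(win.seq) == 41 and win.focal_offset == 20
        assert win.focal_base == seq[99]

    def test_left_clipped_window(self, reference_fasta, reference_seqs):
        seq = reference_seqs["contig1"]
        win = extract_window(reference_fasta, VariantRecord("contig1", 5, seq[4], "A" if seq[4] != "A" else "C"))
        assert len(win.seq) == 25 and win.focal_offset == 4

    def test_right_clipped_window(self, reference_fasta, reference_seqs):
        seq = reference_seqs["contig1"]
        pos = len(seq)
        win = extract_window(reference_fasta, VariantRecord("contig1", pos, seq[-1], "A" if seq[-1] != "A" else "C"))
        assert len(win.seq) == 21 and win.focal_offset == 20

    def test_absent_contig_fails(self, reference_fasta):
        with pytest.raises(KeyError):
            extract_window(reference_fasta, VariantRecord("chrX", 100, "C", "T"))


def hand_window(core: str, focal_offset: int) -> ContextWindow:
    return ContextWindow(seq=core, focal_offset=focal_offset)


class TestTallyAndEnrichment:
    def test_hand_counted_toy_window(self):
        #           0123456789...
        window = "ATCCAGGATCCTTTTTCCAAA"  # TCC at 1,8,15; GGA at 5
        v = VariantRecord("c", 100, "C", "T")
        counts = tally_channel_counts([v], [hand_window(window, 2)])
        key = ("T", "C", "T", "C")  # focal context T_C -> TCC>TTC
        assert counts.mut_channel[key] == 1
        assert counts.mut_class[("C", "T")] == 1
        motifs = counts.motif_counts[("C", "T")]
        assert motifs["TCC"] + motifs[reverse_complement("TCC")] == 4
        assert counts.base_counts[("C", "T")] == window.count("C") + window.count("G")
        e = channel_enrichment(counts, key)
        expected = (1 * counts.base_counts[("C", "T")]) / (1 * 4)
        assert e == pytest.approx(expected)

    def test_enrichment_arithmetic(self):
        counts = ChannelCounts()
        key = ("T", "C", "T", "C")
        counts.mut_channel[key] = 2
        counts.mut_class[("C", "T")] = 4
        counts.motif_counts[("C", "T")] = {"TCC": 6, "GGA": 4}
        counts.base_counts[("C", "T")] = 40
        assert channel_enrichment(counts, key) == pytest.approx(2.0)

    def test_context_proportional_mutations_give_unit_enrichment(self):
        counts = ChannelCounts()
        key = ("T", "C", "T", "C")
        counts.mut_channel[key] = 3
        counts.mut_class[("C", "T")] = 12
        counts.motif_counts[("C", "T")] = {"TCC": 10}
        counts.base_counts[("C", "T")] = 40  # Mut_m/Mut_b = Con_m/Con_b = 1/4
        assert channel_enrichment(counts, key) == pytest.approx(1.0)

    def test_degenerate_cases_yield_zero(self):
        counts = ChannelCounts()
        key = ("T", "C", "T", "C")
        assert channel_enrichment(counts, key) == 0.0  # no mutations at all
        counts.mut_channel[key] = 1
        counts.mut_class[("C", "T")] = 1
        counts.base_counts[("C", "T")] = 10
        assert channel_enrichment(counts, key) == 0.0  # motif never seen

    def test_zero_variants_zero_counts(self):
        counts = tally_channel_counts([], [])
        assert counts.n_variants == 0 and not counts.mut_channel

    def test_purine_channel_equals_its_fold(self, signature):
        v = VariantRecord("c", 100, "C", "T")
        counts = tally_channel_counts([v], [hand_window("ATCCAGGATCCTTTTTCCAAA", 2)])
        assert channel_enrichment(counts, ("T", "C", "T", "C")) == channel_enrichment(
            counts, ("G", "G", "A", "A")
        )

    def test_duplication_scale_invariance(self, reference_fasta, reference_seqs, signature):
        recs = synth_variants(reference_seqs, signature, n=60, f=0.7, seed=3)
        variants = [VariantRecord(c, p, r, a, q, d) for c, p, r, a, q, d in recs]
        windows = [extract_window(reference_fasta, v) for v in variants]
        once = signature_enrichment(tally_channel_counts(variants, windows), signature)
        twice = signature_enrichment(
            tally_channel_counts(variants * 2, windows * 2), signature
        )
        assert twice.uvmse == pytest.approx(once.uvmse, rel=1e-12)

    def test_strand_fold_invariance_of_uvmse(self, reference_fasta, reference_seqs, signature, tmp_path):
        """Reverse-complementing the reference (and remapping the variants)
        leaves every count, hence the score, unchanged."""
        recs = synth_variants(reference_seqs, signature, n=60, f=0.7, seed=4)
        variants = [VariantRecord(c, p, r, a, q, d) for c, p, r, a, q, d in recs]
        windows = [extract_window(reference_fasta, v) for v in variants]
        fwd = signature_enrichment(tally_channel_counts(variants, windows), signature)

        rc_seqs = {c: reverse_complement(s) for c, s in reference_seqs.items()}
        rc_fa = write_fasta(tmp_path / "rc.fasta", rc_seqs)
        rc_fasta = Fasta(str(rc_fa))
        L = len(reference_seqs["contig1"])
        rc_variants = [
            VariantRecord(v.contig, L - v.pos + 1, reverse_complement(v.ref),
                          reverse_complement(v.alt), v.qual, v.depth)
            for v in variants
        ]
        rc_windows = [extract_window(rc_fasta, v) for v in rc_variants]
        rev = signature_enrichment(tally_channel_counts(rc_variants, rc_windows), signature)
        assert rev.uvmse == pytest.approx(fwd.uvmse, rel=1e-12)

    def test_brute_force_recount_on_small_toy(self, reference_fasta, reference_seqs, signature):
        """E_m for every channel matches an independent motif/mutation
        recount done directly on the window strings."""
        recs = synth_variants(reference_seqs, signature, n=10, f=0.5, seed=5)
        variants = [VariantRecord(c, p, r, a, q, d) for c, p, r, a, q, d in recs]
        windows = [extract_window(reference_fasta, v) for v in variants]
        counts = tally_channel_counts(variants, windows)

        def fold(ref, alt):
            return (ref, alt) if ref in "CT" else (reverse_complement(ref), reverse_complement(alt))

        for key in signature.probabilities:
            c5, ref, alt, c3 = key
            if ref not in "CT":
                continue
            t = (ref, alt)
            mut_m = mut_b = con_m = con_b = 0
            for v, w in zip(variants, windows):
                if fold(v.ref, v.alt) != t:
                    continue
                mut_b += 1
                i = w.focal_offset
                ctx = w.seq[i - 1 : i + 2]
                folded_ctx = ctx if v.ref in "CT" else reverse_complement(ctx)
                if folded_ctx == c5 + ref + c3:
                    mut_m += 1
                motif = c5 + ref + c3
                con_m += sum(
                    w.seq[j : j + 3] in (motif, reverse_complement(motif))
                    for j in range(len(w.seq) - 2)
                )
                con_b += sum(b in (ref, reverse_complement(ref)) for b in w.seq)
            expected = (mut_m * con_b) / (mut_b * con_m) if mut_b and con_m else 0.0
            assert channel_enrichment(counts, key) == pytest.approx(expected)


class TestUVMSE:
    def test_degenerate_signature_reduces_to_single_channel(self, reference_fasta, reference_seqs, toy_two_channel_signature):
        from uvsig.tables import ALL_CHANNELS, MutationalSignature

        probs = dict.fromkeys(ALL_CHANNELS, 0.0)
        probs[("T", "C", "T", "C")] = 1.0
        point = MutationalSignature(probs, name="point")
        recs = synth_variants(reference_seqs, toy_two_channel_signature, n=50, f=1.0, seed=6)
        variants = [VariantRecord(c, p, r, a, q, d) for c, p, r, a, q, d in recs]
        windows = [extract_window(reference_fasta, v) for v in variants]
        counts = tally_channel_counts(variants, windows)
        res = signature_enrichment(counts, point)
        assert res.uvmse == pytest.approx(channel_enrichment(counts, ("T", "C", "T", "C")))

    def test_uv_set_scores_above_background_set(self, reference_fasta, reference_seqs, signature):
        def uvmse(f, seed):
            recs = synth_variants(reference_seqs, signature, n=300, f=f, seed=seed)
            variants = [VariantRecord(c, p, r, a, q, d) for c, p, r, a, q, d in recs]
            windows = [extract_window(reference_fasta, v) for v in variants]
            return signature_enrichment(tally_channel_counts(variants, windows), signature).uvmse

        assert uvmse(1.0, 11) > uvmse(0.0, 11)

    def test_uvmse_monotone_in_mixing_fraction(self, reference_fasta, reference_seqs, signature):
        """Monte-Carlo mean UVMSE (5 seeds, n=500) increases with the
        signature mixing fraction f."""

        def mean_uvmse(f):
            vals = []
            for seed in range(5):
                recs = synth_variants(reference_seqs, signature, n=500, f=f, seed=40 + seed)
                variants = [VariantRecord(c, p, r, a, q, d) for c, p, r, a, q, d in recs]
                windows = [extract_window(reference_fasta, v) for v in variants]
                vals.append(
                    signature_enrichment(tally_channel_counts(variants, windows), signature).uvmse
                )
            return float(np.mean(vals))

        curve = [mean_uvmse(f) for f in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(a < b for a, b in zip(curve, curve[1:]))

    def test_weighted_uv_load(self):
        assert weighted_uv_load(100, 0.8) == pytest.approx(80.0)
        assert weighted_uv_load(100, 0.0) == 0.0
        assert weighted_uv_load(0, 2.5) == 0.0
        with pytest.raises(ValueError):
            weighted_uv_load(-1, 1.0)

    def test_score_sample_end_to_end(self, tmp_path, reference, reference_seqs, signature):
        recs = synth_variants(reference_seqs, signature, n=80, f=0.9, seed=12)
        vcf = write_vcf(recs, reference_seqs, tmp_path / "s.vcf")
        res = score_sample(vcf, reference, signature)
        assert res.n_variants_used == 80
        assert res.uvmse > 1.0  # strongly UV-mixed sample is enriched
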