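import numpy as np
import pandas as pd
import pytest

from lncwhiten import SyntheticSpec, generate_dataset
from lncwhiten.identify import (
    classify_position,
    consensus_noncoding,
    filter_structural,
    identify_lncrnas,
    longest_orf,
)
from lncwhiten.index import build_annotation_index
from lncwhiten.model import (
    CodingPotentialCalls,
    ExpressionMatrix,
    GenomicInterval,
    PositionalCategory,
    TranscriptModel,
    ValidationError,
)
from lncwhiten.simulate import plant_novel_transcripts
from oracles import classify_bruteforce, longest_orf_bruteforce


def _tx(tid, exons, strand="+", chrom="chr1", gene=None, biotype="other",
        source="novel"):
    return TranscriptModel(
        tid, gene or f"G_{tid}", chrom, strand,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        source, biotype,
    )


def _tpm(values_by_tid, samples=("s1", "s2")):
    values = pd.DataFrame(values_by_tid, index=list(samples)).T
    metadata = pd.DataFrame(
        {"stage": ["A"] * len(samples), "replicate": range(1, len(samples) + 1)},
        index=list(samples),
    )
    return ExpressionMatrix(values, "TPM", metadata)


class TestFilterStructural:
    """The retention rule: length >= 200, multi-exonic, TPM > 0.1 somewhere."""

    @pytest.mark.parametrize(
        "exons,tpm_values,kept",
        [
            # 150 nt, 2 exons, well expressed -> too short
            ([(0, 75), (200, 275)], [5.0, 5.0], False),
            # 500 nt single exon -> mono-exonic
            ([(0, 500)], [5.0, 5.0], False),
            # 500 nt, 2 exons, max TPM 0.05 -> under-expressed
            ([(0, 250), (400, 650)], [0.05, 0.02], False),
            # exactly 200 nt, 2 exons, 0.2 TPM in one sample -> retained
            ([(0, 100), (300, 400)], [0.2, 0.0], True),
            # TPM exactly at the threshold is NOT above it
            ([(0, 100), (300, 400)], [0.1, 0.1], False),
        ],
    )
    def test_threshold_semantics(self, exons, tpm_values, kept):
        t = _tx("t1", exons)
        tpm = _tpm({"t1": tpm_values})
        retained = filter_structural([t], tpm)
        assert (t in retained) == kept

    def test_missing_id_dropped_with_warning_or_error(self, caplog):
        t = _tx("absent", [(0, 150), (300, 450)])
        tpm = _tpm({"other": [1.0, 1.0]})
        assert filter_structural([t], tpm) == []
        with pytest.raises(ValidationError):
            filter_structural([t], tpm, on_missing="error")


class TestClassifyPosition:
    @pytest.fixture
    def reference(self):
        # one protein-coding gene: exons [1000,1500) and [3000,3500), + strand
        return [
            _tx("ref1", [(1000, 1500), (3000, 3500)], strand="+", gene="HOSTG",
                biotype="protein_coding", source="reference")
        ]

    @pytest.fixture
    def index(self, reference):
        return build_annotation_index(reference)

    def test_no_genes_on_chromosome_is_lincrna(self, index):
        t = _tx("t", [(0, 300), (500, 800)], chrom="chrUn")
        assert classify_position(t, index) == PositionalCategory.LINCRNA
        with pytest.raises(ValidationError):
            classify_position(t, index, strict=True)

    def test_contained_in_single_intron_is_intronic(self, index):
        t = _tx("t", [(1600, 1800), (2000, 2200)], strand="-")
        assert classify_position(t, index) == PositionalCategory.INTRONIC

    def test_opposite_strand_exon_overlap_is_antisense(self, index):
        t = _tx("t", [(1200, 1400), (1700, 1900)], strand="-")
        assert classify_position(t, index) == PositionalCategory.ANTISENSE

    def test_same_strand_partial_overlap_is_sense_overlapping(self, index):
        t = _tx("t", [(900, 1100), (1700, 1900)], strand="+")
        assert classify_position(t, index) == PositionalCategory.SENSE_OVERLAPPING

    def test_exact_intron_chain_match_is_rejected_known(self, index, reference):
        ref = reference[0]
        t = _tx("t", [(e.start, e.end) for e in ref.exons], strand="+")
        assert classify_position(t, index) == PositionalCategory.REJECTED_KNOWN

    def test_body_overlap_without_exon_or_intron_fit_is_rejected(self, index):
        # spans beyond a single intron without touching exons is impossible
        # here, so overlap the body across the intron boundary with no exons hit
        t = _tx("t", [(1600, 2200), (2400, 3600 - 50)], strand="+", chrom="chr1")
        # second exon [2400,3550) overlaps ref exon [3000,3500): same strand
        assert classify_position(t, index) == PositionalCategory.SENSE_OVERLAPPING
        t2 = _tx("t2", [(900, 990), (1600, 2200)], strand="+")
        # no exon overlap, not inside a single intron, touches the body
        assert classify_position(t2, index) == PositionalCategory.REJECTED_KNOWN

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_on_random_genomes(self, seed):
        rng = np.random.default_rng(100 + seed)
        spec = SyntheticSpec(
            n_genes=40, n_annotated_lncrnas=6,
            planted={"lincRNA": 12, "antisense": 6, "intronic": 5,
                     "sense_overlapping": 4, "rejected_known": 3},
        )
        from lncwhiten.simulate import generate_annotation

        reference = generate_annotation(spec, int(rng.integers(2**31)))
        novel, _, _ = plant_novel_transcripts(spec=spec, reference=reference,
                                              seed=int(rng.integers(2**31)))
        index = build_annotation_index(reference)
        for t in novel:
            assert classify_position(t, index) == classify_bruteforce(t, reference)

    def test_invariant_under_coordinate_translation_and_renaming(self, index, reference):
        shift = 10_000
        cases = [
            _tx("a", [(1200, 1400), (1700, 1900)], strand="-"),
            _tx("b", [(1600, 1800), (2000, 2200)], strand="+"),
            _tx("c", [(5000, 5300), (5500, 5800)], strand="+"),
        ]
        shifted_ref = [
            TranscriptModel(
                t.transcript_id, t.gene_id, "other", t.strand,
                tuple(GenomicInterval("other", e.start + shift, e.end + shift,
                                      t.strand) for e in t.exons),
                "reference", t.biotype,
            )
            for t in reference
        ]
        shifted_index = build_annotation_index(shifted_ref)
        for t in cases:
            moved = TranscriptModel(
                t.transcript_id, t.gene_id, "other", t.strand,
                tuple(GenomicInterval("other", e.start + shift, e.end + shift,
                                      t.strand) for e in t.exons),
            )
            assert classify_position(t, index) == classify_position(
                moved, shifted_index
            )


class TestConsensusNoncoding:
    def _calls(self, **overrides):
        base = {p: "noncoding" for p in ("CPC2", "CPAT", "CNCI", "Pfam")}
        base.update(overrides)
        return CodingPotentialCalls({"t1": base})

    def test_all_four_noncoding_is_credible(self):
        assert consensus_noncoding(self._calls(), "t1") is True

    def test_single_coding_call_rejects(self):
        assert consensus_noncoding(self._calls(CNCI="coding"), "t1") is False

    def test_missing_call_is_not_confirmed(self, caplog):
        calls = CodingPotentialCalls(
            {"t1": {"CPC2": "noncoding", "CPAT": "noncoding", "CNCI": "noncoding"}}
        )
        assert consensus_noncoding(calls, "t1") is False

    def test_absent_id_raises(self):
        with pytest.raises(KeyError):
            consensus_noncoding(self._calls(), "t2")

    def test_monotone_adding_coding_never_flips_to_true(self):
        preds = ("CPC2", "CPAT", "CNCI", "Pfam")
        for bits in range(16):
            labels = {
                p: ("coding" if bits >> i & 1 else "noncoding")
                for i, p in enumerate(preds)
            }
            base = consensus_noncoding(CodingPotentialCalls({"t1": labels}), "t1")
            for p in preds:
                worse = dict(labels)
                worse[p] = "coding"
                flipped = consensus_noncoding(
                    CodingPotentialCalls({"t1": worse}), "t1"
                )
                assert not (flipped and not base)


class TestLongestOrf:
    def test_simple_orf(self):
        assert longest_orf("ATGAAATAG") == 2

    def test_no_start_codon(self):
        assert longest_orf("CCCCCCTAGCCC") == 0

    def test_orf_requires_stop(self):
        assert longest_orf("ATGAAAAAA") == 0

    def test_invalid_character_rejected(self):
        with pytest.raises(ValidationError):
            longest_orf("ATGXXX")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 400))))
        assert longest_orf(seq) == longest_orf_bruteforce(seq)


class TestIdentifyLncrnas:
    def test_planted_category_counts_recovered(self):
        spec = SyntheticSpec(
            planted={"lincRNA": 20, "antisense": 10, "intronic": 15,
                     "sense_overlapping": 5, "rejected_known": 4},
        )
        bundle = generate_dataset(spec, 5)
        records, summary = identify_lncrnas(
            bundle.novel, bundle.reference, bundle.tpm, bundle.calls
        )
        assert summary["lincRNA"] == 20
        assert summary["antisense"] == 10
        assert summary["intronic"] == 15
        assert summary["sense_overlapping"] == 5
        assert summary["novel_total"] == 50

    def test_category_counts_partition_total(self, default_bundle):
        records, summary = identify_lncrnas(
            default_bundle.novel, default_bundle.reference,
            default_bundle.tpm, default_bundle.calls,
        )
        cats = ("lincRNA", "antisense", "intronic", "sense_overlapping")
        assert sum(summary[c] for c in cats) == summary["novel_total"]
        assert summary["novel_total"] + summary["annotated_total"] == summary["grand_total"]
        assert len(records) == summary["grand_total"]

    def test_empty_novel_set_yields_only_annotated(self, default_bundle):
        records, summary = identify_lncrnas(
            [], default_bundle.reference, default_bundle.tpm, default_bundle.calls
        )
        assert summary["novel_total"] == 0
        assert all(r.origin == "annotated" for r in records)
        assert all(r.category == PositionalCategory.LINCRNA for r in records)

    def test_coding_flips_remove_exactly_those_transcripts(self):
        spec = SyntheticSpec(coding_flip_fraction=0.1)
        bundle = generate_dataset(spec, 9)
        records, summary = identify_lncrnas(
            bundle.novel, bundle.reference, bundle.tpm, bundle.calls
        )
        got = {r.transcript_id for r in records if r.origin == "novel"}
        assert got == bundle.ledger.expected_retained_novel()
        assert bundle.ledger.flipped_coding  # the flip actually happened
        assert got.isdisjoint(bundle.ledger.flipped_coding)
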