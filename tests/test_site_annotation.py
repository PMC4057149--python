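import numpy as np
import pandas as pd
import pytest

from cescan import (
    GenomicInterval,
    TranscriptInterval,
    TranscriptModel,
    mark_ago_supported,
    mark_conserved,
    project_to_transcript,
    transcript_position_to_genomic,
)
from cescan.io_formats import SITE_COLUMNS
from oracles import per_base_projection


def _model(strand="+", exons=((100, 150), (200, 230))):
    return TranscriptModel(
        "t1", "g1", "chr1", strand,
        exons=tuple(GenomicInterval("chr1", s, e, strand) for s, e in exons),
    )


def _sites(rows):
    """rows: (transcript_id, t_start, t_end)"""
    df = pd.DataFrame(
        [
            [tid, tid, "lncRNA", "m1", "8mer", s, e, 0, e, 40.0, None, None]
            for tid, s, e in rows
        ],
        columns=SITE_COLUMNS,
    )
    return df


class TestProjection:
    def test_intron_spanning_interval_splits(self):
        out = project_to_transcript(_model(), [GenomicInterval("chr1", 140, 210)])
        assert [(o.start, o.end) for o in out] == [(40, 50), (50, 60)]

    def test_intronic_interval_vanishes(self):
        assert project_to_transcript(_model(), [GenomicInterval("chr1", 150, 200)]) == []

    def test_minus_strand_reverses_coordinates(self):
        model = _model("-", exons=((100, 150),))
        out = project_to_transcript(model, [GenomicInterval("chr1", 100, 110)])
        assert [(o.start, o.end) for o in out] == [(40, 50)]

    def test_chromosome_mismatch_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="chr2"):
            out = project_to_transcript(_model(), [GenomicInterval("chr2", 100, 120)])
        assert out == []

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_per_base_oracle_on_random_models(self, strand):
        rng = np.random.default_rng(13)
        for _ in range(30):
            n_ex = int(rng.integers(1, 5))
            starts = np.cumsum(rng.integers(20, 80, size=2 * n_ex)) + 1000
            exons = tuple(
                GenomicInterval("chr1", int(starts[2 * i]), int(starts[2 * i + 1]), strand)
                for i in range(n_ex)
            )
            model = TranscriptModel("t1", "g1", "chr1", strand, exons)
            gmap = per_base_projection(model)
            lo = int(rng.integers(900, starts[-1] + 10))
            hi = lo + int(rng.integers(1, 150))
            out = project_to_transcript(model, [GenomicInterval("chr1", lo, hi)])
            covered = set()
            for iv in out:
                covered.update(range(iv.start, iv.end))
            expected = {tx for g, tx in gmap.items() if lo <= g < hi}
            assert covered == expected
            # round trip: every projected base maps back inside the input interval
            for tx_pos in covered:
                assert lo <= transcript_position_to_genomic(model, tx_pos) < hi


class TestConservation:
    def test_seed_containment_is_conserved(self):
        out = mark_conserved(_sites([("t1", 100, 108)]), [TranscriptInterval("t1", 90, 120)])
        assert list(out["conserved"]) == [True]

    def test_short_block_never_confers(self):
        """Blocks below 8 bases are discarded; an overlapping site is False."""
        out = mark_conserved(_sites([("t1", 100, 106)]), [TranscriptInterval("t1", 100, 107)])
        assert list(out["conserved"]) == [False]

    def test_uncovered_transcript_stays_unknown(self):
        out = mark_conserved(
            _sites([("t1", 10, 18), ("t2", 10, 18)]), [TranscriptInterval("t1", 0, 50)]
        )
        assert list(out["conserved"]) == [True, None]

    def test_partial_overlap_is_not_containment(self):
        out = mark_conserved(_sites([("t1", 100, 108)]), [TranscriptInterval("t1", 104, 130)])
        assert list(out["conserved"]) == [False]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            sites = _sites([("t1", int(s), int(s) + 7) for s in rng.integers(0, 400, 30)])
            blocks = [
                TranscriptInterval("t1", int(a), int(a) + int(w))
                for a, w in zip(rng.integers(0, 400, 15), rng.integers(4, 40, 15))
            ]
            out = mark_conserved(sites, blocks)
            for flag, (_, s, e) in zip(out["conserved"], sites[["transcript_id", "t_start", "t_end"]].itertuples(index=False)):
                brute = any(b.start <= s and e <= b.end for b in blocks if len(b) >= 8)
                assert flag == brute


class TestAgoSupport:
    def test_one_base_overlap_suffices(self):
        out = mark_ago_supported(_sites([("t1", 10, 18)]), [TranscriptInterval("t1", 17, 40)])
        assert list(out["ago_supported"]) == [True]

    def test_half_open_adjacency_is_no_overlap(self):
        out = mark_ago_supported(_sites([("t1", 10, 18)]), [TranscriptInterval("t1", 18, 40)])
        assert list(out["ago_supported"]) == [False]

    def test_no_ago_data_leaves_unknown(self):
        out = mark_ago_supported(_sites([("t1", 10, 18)]), [])
        assert list(out["ago_supported"]) == [None]

    def test_annotation_preserves_cardinality_and_columns(self):
        sites = _sites([("t1", 10, 18), ("t1", 50, 58), ("t2", 5, 13)])
        out = mark_ago_supported(
            mark_conserved(sites, [TranscriptInterval("t1", 0, 100)]),
            [TranscriptInterval("t2", 0, 6)],
        )
        assert len(out) == len(sites)
        assert list(out["t_start"]) == list(sites["t_start"])
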