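"""Transformed-realignment detection: cluster rules, merging, motif, QC.

Includes a brute-force oracle: on a small genome every pool read is tried
at every offset and orientation in transformed space, mismatch runs are
enumerated and the three cluster rules applied independently of the
seed-based implementation.
"""

import numpy as np
import pandas as pd
import pytest

from conftest import random_seq
from thermedit.io_alignment import AlignParams, Genome, align_reads, revcomp
from thermedit.hyper_editing import (
    HyperEditedCluster,
    HyperParams,
    MismatchEvent,
    TransformedRealigner,
    a2g_share,
    collect_sites,
    compute_motif,
    detect_editing,
    detect_hyper_edited_reads,
    merge_clusters_to_regions,
    qc_mismatch_spectrum,
    strand_split,
    transform,
)
from thermedit.simulate import (
    SimConfig,
    generate_genome,
    plant_editing_clusters,
    simulate_reads,
)


class TestTransform:
    def test_examples(self):
        assert transform("GATTACA", "A", "G") == "GGTTGCG"
        assert transform("CCGG", "A", "G") == "CCGG"
        assert transform("GATTACA", "A", "G").count("A") == 0

    def test_length_preserved(self):
        assert len(transform("GATTACA", "T", "C")) == 7

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            transform("ACGT", "A", "A")


def _read_with_edits(genome, start, length, offsets, strand="+", to="G"):
    """Genome substring with A->G conversions at the given read offsets."""
    seq = list(genome.fetch("c1", start, start + length))
    for off in offsets:
        seq[off] = to
    read = "".join(seq)
    return read if strand == "+" else revcomp(read)


@pytest.fixture(scope="module")
def small_genome():
    rng = np.random.default_rng(77)
    return Genome({"c1": random_seq(rng, 30_000)})


class TestClusterRules:
    def find_locus(self, genome, lo, hi, n):
        """First read start whose [lo, hi) window holds >= n adenosines."""
        for start in range(1000, 25_000, 250):
            seq = genome.fetch("c1", start, start + 100)
            offs = [i for i in range(lo, hi) if seq[i] == "A"]
            if len(offs) >= n:
                return start, offs[:n]
        raise AssertionError("no suitable locus in fixture genome")

    def test_dense_cluster_detected_with_all_events(self, small_genome):
        start, offs = self.find_locus(small_genome, 30, 65, 6)
        read = _read_with_edits(small_genome, start, 100, offs)
        clusters, _ = detect_hyper_edited_reads(
            [("r1", read, "I" * 100)], small_genome, ("A", "G")
        )
        assert len(clusters) == 1
        assert clusters[0].n_edits == 6
        assert {e.pos for e in clusters[0].events} == {start + o for o in offs}

    def test_edits_only_near_read_end_rejected(self, small_genome):
        start, offs = self.find_locus(small_genome, 95, 100, 2)
        read = _read_with_edits(small_genome, start, 100, offs)
        clusters, _ = detect_hyper_edited_reads(
            [("r1", read, "I" * 100)], small_genome, ("A", "G"),
            HyperParams(min_edits=1, end_exclusion=6),
        )
        assert clusters == []

    def test_narrow_span_rejected(self, small_genome):
        # 2 edits spanning < 10% of a 100-nt read
        start, offs = self.find_locus(small_genome, 40, 48, 2)
        assert offs[-1] - offs[0] + 1 < 10
        read = _read_with_edits(small_genome, start, 100, offs)
        clusters, _ = detect_hyper_edited_reads(
            [("r1", read, "I" * 100)], small_genome, ("A", "G"),
            HyperParams(min_edits=2),
        )
        assert clusters == []

    def test_low_quality_mismatches_ignored(self, small_genome):
        start, offs = self.find_locus(small_genome, 20, 80, 5)
        read = _read_with_edits(small_genome, start, 100, offs)
        qual = list("I" * 100)
        for o in offs:
            qual[o] = "#"  # Phred 2
        clusters, _ = detect_hyper_edited_reads(
            [("r1", read, "".join(qual))], small_genome, ("A", "G")
        )
        assert clusters == []

    def test_minus_strand_editing_found_via_tc_run(self, small_genome):
        # read sequenced from the minus strand of a minus-strand transcript
        for s0 in range(9000, 25_000, 250):
            seq = small_genome.fetch("c1", s0, s0 + 100)
            offs = [i for i in range(25, 75) if seq[i] == "T"]
            if len(offs) >= 5 and offs[4] - offs[0] + 1 >= 10:
                break
        offs = offs[:5]
        read_plus = list(seq)
        for o in offs:
            read_plus[o] = "C"  # A->G on minus appears as T->C on plus
        read = revcomp("".join(read_plus))
        clusters, _ = detect_editing([("r1", read, "I" * 100)], small_genome)
        assert len(clusters) == 1
        assert clusters[0].strand == "-"
        assert clusters[0].mismatch_type == ("T", "C")

    def test_sensitivity_monotone_in_thresholds(self, small_genome, rng):
        pool = []
        for k in range(30):
            start = 100 + k * 900
            seq = small_genome.fetch("c1", start, start + 100)
            offs = [i for i in range(10, 90) if seq[i] == "A"][:6]
            if len(offs) < 4 or offs[-1] - offs[0] < 12:
                continue
            pool.append((f"r{k}", _read_with_edits(small_genome, start, 100, offs), "I" * 100))
        base = len(detect_hyper_edited_reads(pool, small_genome, ("A", "G"))[0])
        stricter_edits = len(
            detect_hyper_edited_reads(
                pool, small_genome, ("A", "G"), HyperParams(min_edits=6)
            )[0]
        )
        stricter_quality = len(
            detect_hyper_edited_reads(
                pool, small_genome, ("A", "G"), HyperParams(quality_min=41)
            )[0]
        )
        assert stricter_edits <= base
        assert stricter_quality <= base


def _cluster(contig, start, end, strand="+", rid="r"):
    events = [
        MismatchEvent(rid, contig, start, 10, "A", "G", 40),
        MismatchEvent(rid, contig, end - 1, 40, "A", "G", 40),
    ]
    return HyperEditedCluster(
        read_id=rid, contig=contig, start=start, end=end, strand=strand,
        read_length=100, mismatch_type=("A", "G"), events=events,
    )


class TestMergeClusters:
    def test_gap_nine_merges(self):
        regions = merge_clusters_to_regions(
            [_cluster("c1", 100, 141), _cluster("c1", 150, 181)]
        )
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (100, 181)

    def test_gap_twenty_merges_but_twentyone_splits(self):
        # half-open ends: cluster [100,141) then next start 161 -> gap 20
        merged = merge_clusters_to_regions(
            [_cluster("c1", 100, 141), _cluster("c1", 161, 200)], max_gap=20
        )
        assert len(merged) == 1
        split = merge_clusters_to_regions(
            [_cluster("c1", 100, 141), _cluster("c1", 162, 200)], max_gap=20
        )
        assert len(split) == 2

    def test_single_cluster_region_equals_cluster(self):
        regions = merge_clusters_to_regions([_cluster("c1", 300, 333)])
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (300, 333)

    def test_strands_and_contigs_not_merged_together(self):
        regions = merge_clusters_to_regions(
            [
                _cluster("c1", 100, 140, "+"),
                _cluster("c1", 145, 180, "-"),
                _cluster("c2", 100, 140, "+"),
            ]
        )
        assert len(regions) == 3

    def test_empty_input(self):
        assert merge_clusters_to_regions([]) == []

    def test_region_event_counts_conserved(self, aligned_dataset):
        clusters = aligned_dataset["T18"]["clusters"]
        regions = merge_clusters_to_regions(clusters)
        assert sum(r.n_events for r in regions) == sum(c.n_edits for c in clusters)

    def test_every_site_within_a_region(self, aligned_dataset):
        clusters = aligned_dataset["T18"]["clusters"]
        sites = aligned_dataset["T18"]["sites"]
        regions = merge_clusters_to_regions(clusters)
        by_strand = {}
        for r in regions:
            by_strand.setdefault((r.contig, r.strand), []).append((r.start, r.end))
        for row in sites.itertuples(index=False):
            spans = by_strand[(row.contig, row.strand)]
            assert any(s <= row.pos < e for s, e in spans)


class TestCollectSites:
    def test_two_reads_one_site(self):
        ev = lambda rid: MismatchEvent(rid, "c1", 500, 20, "A", "G", 40)
        clusters = [
            HyperEditedCluster(rid, "c1", 480, 520, "+", 100, ("A", "G"),
                               [ev(rid),
                                MismatchEvent(rid, "c1", 480 + i, 10, "A", "G", 40)])
            for i, rid in enumerate(["r1", "r2"])
        ]
        sites, summary = collect_sites(clusters)
        shared = sites[sites["pos"] == 500]
        assert shared["n_events"].iloc[0] == 2

    def test_events_per_site_unit_support(self):
        clusters = [
            HyperEditedCluster(
                f"r{i}", "c1", 100 * i, 100 * i + 30, "+", 100, ("A", "G"),
                [MismatchEvent(f"r{i}", "c1", 100 * i + j, 10 + j, "A", "G", 40)
                 for j in range(1)],
            )
            for i in range(10)
        ]
        _, summary = collect_sites(clusters)
        assert summary["n_sites"] == 10
        assert summary["events_per_site"] == 1.0

    def test_higher_rate_regime_has_more_events_per_site(self, aligned_dataset):
        high = aligned_dataset["T18"]["summary"]["events_per_site"]
        low = aligned_dataset["T29"]["summary"]["events_per_site"]
        assert high > low


class TestBruteForceOracle:
    def _oracle_clusters(self, pool, genome, mismatch_type, params):
        """Try every read at every offset/orientation in transformed space."""
        frm, to = mismatch_type
        out = []
        tseq = {n: transform(s, frm, to) for n, s in genome.contigs.items()}
        arrs = {n: np.frombuffer(s.encode(), dtype=np.uint8) for n, s in tseq.items()}
        for rid, seq, qual in pool:
            L = len(seq)
            budget = params.align.budget(L)
            best = budget + 1
            hits = []
            for orient in "+-":
                oriented = seq if orient == "+" else revcomp(seq)
                tread = np.frombuffer(
                    transform(oriented, frm, to).encode(), dtype=np.uint8
                )
                for contig, arr in arrs.items():
                    n_off = len(arr) - L + 1
                    counts = np.zeros(n_off, dtype=np.int32)
                    for k in range(L):
                        counts += arr[k : k + n_off] != tread[k]
                    m = int(counts.min())
                    if m < best:
                        best = m
                        hits = [(contig, int(i), orient) for i in np.flatnonzero(counts == m)]
                    elif m == best:
                        hits += [(contig, int(i), orient) for i in np.flatnonzero(counts == m)]
            if best > budget or len(set(hits)) != 1:
                continue
            contig, start, orient = hits[0]
            oriented = seq if orient == "+" else revcomp(seq)
            ref = genome.contigs[contig][start : start + L]
            events = []
            for i in range(L):
                if ref[i] == frm and oriented[i] == to:
                    rp = i if orient == "+" else L - 1 - i
                    if ord(qual[rp]) - 33 < params.quality_min:
                        continue
                    if rp < params.end_exclusion or rp >= L - params.end_exclusion:
                        continue
                    events.append((start + i, rp))
            if len(events) < params.min_edits:
                continue
            first, last = min(e[0] for e in events), max(e[0] for e in events)
            if last - first + 1 < params.span_fraction * L:
                continue
            out.append((rid, contig, first, last + 1, tuple(sorted(e[0] for e in events))))
        return sorted(out)

    def test_identical_cluster_set_on_small_genome(self):
        cfg = SimConfig(
            genome_length=40_000, n_clusters=6, per_site_edit_rate={"C": 0.8},
            coverage=8, seq_error_rate=0.0, seed=21,
        )
        genome, _ = generate_genome(cfg)
        truth = plant_editing_clusters(genome, cfg)
        reads, _ = simulate_reads(genome, truth, "C", cfg)
        res = align_reads(reads, genome)
        assert len(res.unaligned) > 10
        params = HyperParams()
        for mt in [("A", "G"), ("T", "C")]:
            clusters, _ = detect_hyper_edited_reads(
                res.unaligned, genome, mt, params
            )
            got = sorted(
                (c.read_id, c.contig, c.start, c.end,
                 tuple(sorted(e.pos for e in c.events)))
                for c in clusters
            )
            expected = self._oracle_clusters(res.unaligned, genome, mt, params)
            assert got == expected

    def test_detection_deterministic(self, small_genome):
        offs_reads = []
        seq = small_genome.fetch("c1", 5000, 5100)
        offs = [i for i in range(20, 80) if seq[i] == "A"][:5]
        offs_reads.append(("r1", _read_with_edits(small_genome, 5000, 100, offs), "I" * 100))
        c1, _ = detect_hyper_edited_reads(offs_reads, small_genome, ("A", "G"))
        c2, _ = detect_hyper_edited_reads(offs_reads, small_genome, ("A", "G"))
        assert [(c.start, c.end, c.n_edits) for c in c1] == [
            (c.start, c.end, c.n_edits) for c in c2
        ]


@pytest.fixture(scope="module")
def spectrum(sim_dataset, aligned_dataset):
    pool = (
        aligned_dataset["T18"]["alignment"].unaligned
        + aligned_dataset["T29"]["alignment"].unaligned
    )
    genome = sim_dataset["genome"]
    return qc_mismatch_spectrum(pool, genome, HyperParams(),
                                aligned_dataset["realigner"])


class TestQCSpectrum:

    def test_a2g_dominates_when_only_a2g_planted(self, spectrum):
        df, _ = spectrum
        assert a2g_share(df) >= 0.95

    def test_strand_split_balanced(self, aligned_dataset):
        sites = pd.concat(
            [aligned_dataset[c]["sites"] for c in ("T18", "T29")]
        ).drop_duplicates(["contig", "pos", "strand"])
        assert len(sites) >= 200
        assert 0.45 <= strand_split(sites) <= 0.55

    def test_read_position_histogram_respects_end_exclusion(self, spectrum):
        _, hist = spectrum
        assert hist["read_pos"].min() >= 6
        assert hist["read_pos"].max() <= 93

    def test_no_edits_no_errors_empty_spectrum(self):
        cfg = SimConfig(
            genome_length=30_000, n_clusters=2, per_site_edit_rate={"C": 0.0},
            coverage=3, seq_error_rate=0.0, seed=5,
        )
        genome, _ = generate_genome(cfg)
        truth = plant_editing_clusters(genome, cfg)
        reads, _ = simulate_reads(genome, truth, "C", cfg)
        res = align_reads(reads, genome)
        df, _ = qc_mismatch_spectrum(res.unaligned, genome)
        assert df["n_sites"].sum() == 0


class TestMotif:
    def test_center_is_pure_adenosine(self, sim_dataset, aligned_dataset):
        sites = aligned_dataset["T18"]["sites"]
        pfm, _ = compute_motif(sites, sim_dataset["genome"])
        assert pfm.loc[0, "A"] == 1.0

    def test_rows_sum_to_one(self, sim_dataset, aligned_dataset):
        pfm, _ = compute_motif(
            aligned_dataset["T18"]["sites"], sim_dataset["genome"]
        )
        assert np.allclose(pfm.sum(axis=1), 1.0)

    def test_planted_bias_recovered(self):
        # isolated sites (one per cluster), so offsets beyond +-1 stay
        # uniform genomic background
        cfg = SimConfig(
            genome_length=3_000_000, n_clusters=1000, sites_per_cluster=(1, 1),
            motif_g_upstream=0.05, motif_g_downstream=0.40, seed=3,
        )
        genome, _ = generate_genome(cfg)
        truth = plant_editing_clusters(genome, cfg)
        pfm, skipped = compute_motif(truth.sites, genome)
        assert skipped == 0
        assert 0.03 <= pfm.loc[-1, "G"] <= 0.08
        assert 0.33 <= pfm.loc[1, "G"] <= 0.47
        # background offsets stay near uniform
        for off in (-5, -4, -3, 3, 4, 5):
            for b in "ACGT":
                assert abs(pfm.loc[off, b] - 0.25) < 0.03

    def test_empty_sites_rejected(self, sim_dataset):
        with pytest.raises(ValueError):
            compute_motif(pd.DataFrame(columns=["contig", "pos", "strand"]),
                          sim_dataset["genome"])
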