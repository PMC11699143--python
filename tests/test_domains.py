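"""Domain calling, overlap matrices, borders and meta-profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wrapseq import (
    DomainSet,
    GenomeLayout,
    SignalTrack,
    border_profile,
    call_domains,
    list_borders,
    overlap_fraction,
    read_bed4,
    region_profile,
    write_bed4,
)
from wrapseq.domains import _runs, segment_signs


def track_of(signs_or_vals, bin_size=1000):
    vals = np.asarray(signs_or_vals, dtype=float)
    layout = GenomeLayout([("chr1", len(vals) * bin_size)], bin_size)
    return SignalTrack(layout, vals)


def domain_set(rows, labels=("Ti", "Lo")):
    return DomainSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]),
                     labels)


# -- independent oracle for the absorption rule ----------------------------

def brute_force_segmentation(signs, vals, min_size):
    """Re-derive segmentation from the stated rule, bin-label style.

    Keeps a per-bin label array and rebuilds runs from scratch every
    iteration: absorb the shortest (leftmost on ties) run below min_size
    into the flank whose bins have the larger |mean|, left on ties.
    """
    labels = list(signs)
    while True:
        runs = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                runs.append((start, i))
                start = i
        if len(runs) <= 1:
            break
        short = [(stop - s, k) for k, (s, stop) in enumerate(runs)
                 if stop - s < min_size]
        if not short:
            break
        _, k = min(short)
        s, stop = runs[k]
        if k == 0:
            new = labels[runs[1][0]]
        elif k == len(runs) - 1:
            new = labels[runs[k - 1][0]]
        else:
            lm = abs(np.mean([vals[i] for i in range(*runs[k - 1])]))
            rm = abs(np.mean([vals[i] for i in range(*runs[k + 1])]))
            new = labels[runs[k - 1][0]] if lm >= rm else labels[runs[k + 1][0]]
        for i in range(s, stop):
            labels[i] = new
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, labels[start]))
            start = i
    return out


class TestCallDomains:
    def test_two_sign_runs_two_domains(self):
        ds = call_domains(track_of([1, 1, 1, -1, -1]), min_size_bp=1000,
                          smooth_span=0)
        assert [(d.start, d.end, d.label) for d in ds] == [
            (0, 3000, "Ti"), (3000, 5000, "Lo")
        ]

    def test_all_positive_single_domain(self):
        ds = call_domains(track_of([0.5] * 6), min_size_bp=1000, smooth_span=0)
        assert len(ds) == 1
        assert list(ds)[0].label == "Ti"
        assert list(ds)[0].end == 6000

    def test_short_run_absorbed(self):
        # one negative bin between positives, min_size 2 bins -> absorbed
        ds = call_domains(track_of([1, 1, -1, 1, 1]), min_size_bp=2000,
                          smooth_span=0)
        assert len(ds) == 1 and list(ds)[0].label == "Ti"

    def test_zero_bins_take_left_neighbor_sign(self):
        ds = call_domains(track_of([1, 0, -1]), min_size_bp=1000, smooth_span=0)
        assert [(d.end, d.label) for d in ds] == [(2000, "Ti"), (3000, "Lo")]

    def test_single_missing_gap_bridged_larger_gap_splits(self):
        vals = [1, 1, np.nan, 1, 1, np.nan, np.nan, 1, 1]
        ds = call_domains(track_of(vals), min_size_bp=1000, smooth_span=0)
        spans = [(d.start, d.end) for d in ds]
        assert spans == [(0, 5000), (7000, 9000)]

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="all-missing"):
            call_domains(track_of([np.nan] * 5), smooth_span=0)

    def test_idempotent_on_indicator_track(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=60)
        ds = call_domains(track_of(vals), min_size_bp=3000, smooth_span=0)
        indicator = np.where(
            sum((np.arange(60) >= d.start // 1000) & (np.arange(60) < d.end // 1000)
                for d in ds if d.label == "Ti").astype(bool), 1.0, -1.0)
        ds2 = call_domains(track_of(indicator), min_size_bp=3000, smooth_span=0)
        assert ds.frame[["chrom", "start", "end", "label"]].equals(
            ds2.frame[["chrom", "start", "end", "label"]])

    def test_complementarity(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=200)
        ds = call_domains(track_of(vals), min_size_bp=3000, smooth_span=0)
        assert ds.total_bp("Ti") + ds.total_bp("Lo") == 200 * 1000

    @pytest.mark.parametrize("min_size", [1, 2, 3])
    def test_equals_brute_force_for_all_sign_strings(self, min_size):
        rng = np.random.default_rng(123)
        for n in range(1, 13):
            for bits in itertools.product([1, -1], repeat=n):
                vals = np.array(bits) * rng.uniform(0.5, 2.0, size=n)
                expected = brute_force_segmentation(list(bits), vals, min_size)
                got = segment_signs(np.array(bits), vals, min_size)
                assert got == expected, (bits, min_size)


class TestOverlapFraction:
    def test_self_overlap_identity(self):
        ds = domain_set([("chr1", 0, 1000, "Ti"), ("chr1", 1000, 2000, "Lo")])
        m = overlap_fraction(ds, ds)
        assert m.loc["Ti", "Ti"] == 1.0 and m.loc["Lo", "Lo"] == 1.0
        assert m.loc["Ti", "Lo"] == 0.0 and m.loc["Lo", "Ti"] == 0.0

    def test_half_overlap(self):
        q = domain_set([("chr1", 0, 1000, "Ti")])
        r = domain_set([("chr1", 500, 1500, "A")], labels=("A", "B"))
        m = overlap_fraction(q, r)
        assert m.loc["A", "Ti"] == pytest.approx(0.5)

    def test_empty_set_errors(self):
        ds = domain_set([("chr1", 0, 1000, "Ti")])
        empty = DomainSet(pd.DataFrame(columns=["chrom", "start", "end", "label"]),
                          ("A", "B"))
        with pytest.raises(ValueError, match="empty"):
            overlap_fraction(empty, ds)

    def test_matches_bitmap_oracle_and_row_sums(self):
        rng = np.random.default_rng(17)
        genome_len = 5000
        for _ in range(25):
            def random_domains(labels):
                cuts = np.sort(rng.choice(np.arange(100, genome_len, 100),
                                          size=6, replace=False))
                edges = [0, *cuts.tolist(), genome_len]
                drop = rng.random(len(edges) - 1) < 0.2
                rows = []
                for k in range(len(edges) - 1):
                    if drop[k]:
                        continue  # leave uncovered gaps
                    row = ["chr1", edges[k], edges[k + 1], labels[k % 2]]
                    # merge contiguous same-label pieces to satisfy maximality
                    if rows and rows[-1][2] == row[1] and rows[-1][3] == row[3]:
                        rows[-1][2] = row[2]
                    else:
                        rows.append(row)
                return domain_set([tuple(r) for r in rows], labels=labels)

            q = random_domains(("Ti", "Lo"))
            r = random_domains(("A", "B"))
            m = overlap_fraction(q, r)
            # per-base bitmap oracle
            qmap = np.zeros(genome_len, dtype="U2")
            for d in q:
                qmap[d.start:d.end] = d.label
            rmap = np.zeros(genome_len, dtype="U2")
            for d in r:
                rmap[d.start:d.end] = d.label
            for rl in ("A", "B"):
                denom = (rmap == rl).sum()
                if denom == 0:
                    assert m.loc[rl].isna().all()
                    continue
                for ql in ("Ti", "Lo"):
                    expect = ((rmap == rl) & (qmap == ql)).sum() / denom
                    assert m.loc[rl, ql] == pytest.approx(expect)
            assert (m.sum(axis=1) <= 1 + 1e-12).all()


class TestBorders:
    def test_alternating_three_domains(self):
        ds = domain_set([("chr1", 0, 1000, "Ti"), ("chr1", 1000, 2000, "Lo"),
                         ("chr1", 2000, 3000, "Ti")])
        assert list_borders(ds, ("Ti", "Lo"))["pos"].tolist() == [1000]
        assert list_borders(ds, ("Lo", "Ti"))["pos"].tolist() == [2000]

    def test_single_domain_no_borders(self):
        ds = domain_set([("chr1", 0, 3000, "Ti")])
        assert len(list_borders(ds, ("Ti", "Lo"))) == 0

    def test_gap_junctions_are_not_borders(self):
        ds = domain_set([("chr1", 0, 1000, "Ti"), ("chr1", 2000, 3000, "Lo")])
        assert len(list_borders(ds, ("Ti", "Lo"))) == 0

    def test_simulated_genome_matches_adjacency_enumeration(self):
        rng = np.random.default_rng(21)
        rows, pos = [], 0
        labels = []
        for k in range(20):
            length = int(rng.integers(1, 5)) * 1000
            label = "Ti" if k % 2 == 0 else "Lo"
            rows.append(("chr1", pos, pos + length, label))
            labels.append(label)
            pos += length
        ds = domain_set(rows)
        expect_ti_lo = sum(1 for a, b in zip(labels, labels[1:])
                           if (a, b) == ("Ti", "Lo"))
        assert len(list_borders(ds, ("Ti", "Lo"))) == expect_ti_lo


class TestBorderProfile:
    def test_step_track_profile(self):
        t = track_of([-1, -1, -1, 1, 1, 1])
        borders = pd.DataFrame({"chrom": ["chr1"], "pos": [3000]})
        prof = border_profile(t, borders, 3000)
        assert prof.mean_profile() == pytest.approx([-1, -1, -1, 1, 1, 1])
        assert prof.offsets.tolist() == [-3000, -2000, -1000, 0, 1000, 2000]

    def test_window_beyond_chromosome_padded(self):
        t = track_of([1.0] * 6)
        borders = pd.DataFrame({"chrom": ["chr1"], "pos": [2000]})
        prof = border_profile(t, borders, 3000)
        assert np.isnan(prof.matrix[0, 0])
        assert prof.matrix[0, 1:] == pytest.approx([1.0] * 5)

    def test_reverse_flips_columns(self):
        t = track_of([0, 1, 2, 3, 4, 5])
        borders = pd.DataFrame({"chrom": ["chr1"], "pos": [3000]})
        fwd = border_profile(t, borders, 3000)
        rev = border_profile(t, borders, 3000, reverse=True)
        assert rev.matrix[0].tolist() == fwd.matrix[0][::-1].tolist()

    def test_zero_borders_errors(self):
        t = track_of([1.0] * 6)
        with pytest.raises(ValueError, match="no borders"):
            border_profile(t, pd.DataFrame(columns=["chrom", "pos"]), 2000)

    def test_noisy_steps_recover_mean_within_sem(self):
        rng = np.random.default_rng(33)
        n_borders, nbins = 50, 40
        layout = GenomeLayout([(f"c{i}", nbins * 1000) for i in range(n_borders)],
                              1000)
        vals = []
        for i in range(n_borders):
            step = np.where(np.arange(nbins) < nbins // 2, -1.0, 1.0)
            vals.append(step + rng.normal(0, 0.5, nbins))
        t = SignalTrack(layout, np.concatenate(vals))
        borders = pd.DataFrame({"chrom": [f"c{i}" for i in range(n_borders)],
                                "pos": [nbins // 2 * 1000] * n_borders})
        prof = border_profile(t, borders, 5000)
        mean = prof.mean_profile()
        sem = 0.5 / np.sqrt(n_borders)
        truth = np.where(prof.offsets < 0, -1.0, 1.0)
        assert np.abs(mean - truth).max() < 3 * sem


class TestRegionProfile:
    def test_constant_track_constant_matrix(self):
        t = track_of([2.0] * 20)
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [4000],
                                "end": [14000], "strand": ["+"]})
        for mode, kw in (("scaled-body", {"n_cols": 5}),
                         ("anchored", {"flank_bp": 3000})):
            mat = region_profile(t, regions, mode=mode, **kw)
            assert np.allclose(mat, 2.0)

    def test_minus_strand_mirrors_plus(self):
        t = track_of(np.arange(20, dtype=float))
        plus = pd.DataFrame({"chrom": ["chr1"], "start": [4000], "end": [12000],
                             "strand": ["+"]})
        minus = plus.assign(strand="-")
        mp = region_profile(t, plus, mode="scaled-body", n_cols=8)
        mm = region_profile(t, minus, mode="scaled-body", n_cols=8)
        assert mp[0].tolist() == mm[0][::-1].tolist()

    def test_anchored_peak_downstream_of_tss(self):
        # 100 genes, each with a +1 bump in the first bin after the TSS
        rng = np.random.default_rng(55)
        n_genes, nbins = 100, 30
        layout = GenomeLayout([(f"g{i}", nbins * 1000) for i in range(n_genes)],
                              1000)
        vals = []
        tss_bin = 10
        for i in range(n_genes):
            v = rng.normal(0, 0.1, nbins)
            v[tss_bin] += 1.0
            vals.append(v)
        t = SignalTrack(layout, np.concatenate(vals))
        regions = pd.DataFrame({
            "chrom": [f"g{i}" for i in range(n_genes)],
            "start": [tss_bin * 1000] * n_genes,
            "end": [(tss_bin + 10) * 1000] * n_genes,
            "strand": ["+"] * n_genes,
        })
        mat = region_profile(t, regions, mode="anchored", flank_bp=5000)
        mean = np.nanmean(mat, axis=0)
        assert np.argmax(mean) == 5  # first downstream column

    def test_unknown_chromosome_skipped_with_warning(self):
        t = track_of([1.0] * 6)
        regions = pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [2000],
                                "strand": ["+"]})
        with pytest.warns(UserWarning, match="unknown chromosome"):
            mat = region_profile(t, regions, mode="scaled-body", n_cols=4)
        assert mat.shape == (0, 4)


def test_domain_set_rejects_adjacent_same_label():
    with pytest.raises(ValueError, match="maximal"):
        domain_set([("chr1", 0, 1000, "Ti"), ("chr1", 1000, 2000, "Ti")])


def test_bed4_roundtrip(tmp_path):
    ds = domain_set([("chr1", 0, 1000, "Ti"), ("chr1", 1000, 2000, "Lo")])
    p = tmp_path / "d.bed"
    write_bed4(ds, p)
    back = read_bed4(p, ("Ti", "Lo"))
    assert back.frame[["chrom", "start", "end", "label"]].equals(
        ds.frame[["chrom", "start", "end", "label"]])


def test_runs_helper():
    assert _runs(np.array([1, 1, -1])) == [[0, 2, 1], [2, 3, -1]]
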