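"""Filter rules: boundary semantics, brute-force equivalence, invariants."""

import numpy as np
import pytest

from gbsphylo.filters import (
    DEFAULT_ORDER,
    IDENTITY_CONFIG,
    FilterConfig,
    apply_filters,
    drop_invariant,
    filter_depth,
    filter_het,
    filter_maf,
    filter_sample_missing,
    filter_site_missing,
    prune_linked,
)
from gbsphylo.genotype import MISSING

from conftest import make_matrix


# -------------------------------------------------- brute-force oracles
def oracle_site_missing(m, thr):
    keep = []
    for j in range(m.n_sites):
        miss = sum(1 for i in range(m.n_samples) if m.genotypes[i, j] == MISSING)
        keep.append(miss / m.n_samples <= thr)
    return keep


def oracle_sample_missing(m, thr):
    keep = []
    for i in range(m.n_samples):
        miss = sum(1 for j in range(m.n_sites) if m.genotypes[i, j] == MISSING)
        keep.append(miss / m.n_sites <= thr)
    return keep


def oracle_maf(m, thr):
    keep = []
    for j in range(m.n_sites):
        calls = [int(g) for g in m.genotypes[:, j] if g != MISSING]
        if not calls:
            keep.append(False)
            continue
        alt = sum(calls)
        maf = min(alt, 2 * len(calls) - alt) / (2 * len(calls))
        keep.append(maf >= thr)
    return keep


def oracle_het(m, lo, hi=None):
    keep = []
    for j in range(m.n_sites):
        calls = [int(g) for g in m.genotypes[:, j] if g != MISSING]
        if not calls:
            keep.append(False)
            continue
        h = calls.count(1) / len(calls)
        ok = (lo is None or h >= lo) and (hi is None or h <= hi)
        keep.append(ok)
    return keep


def oracle_depth_floor(m, thr):
    """(kept site flags, masked genotype grid) under a depth floor."""
    genos = m.genotypes.copy()
    for i in range(m.n_samples):
        for j in range(m.n_sites):
            if genos[i, j] != MISSING and m.depths[i, j] < thr:
                genos[i, j] = MISSING
    keep = [
        any(genos[i, j] != MISSING for i in range(m.n_samples))
        for j in range(m.n_sites)
    ]
    return keep, genos


def oracle_invariant(m):
    keep = []
    for j in range(m.n_sites):
        calls = {int(g) for g in m.genotypes[:, j] if g != MISSING}
        keep.append(not (calls <= {0} or calls <= {2}))
    return keep


def oracle_prune(m, dist):
    removed = set()
    n_missing = {
        j: sum(1 for i in range(m.n_samples) if m.genotypes[i, j] == MISSING)
        for j in range(m.n_sites)
    }
    for contig in m.sites["contig"].unique():
        idx = [
            j
            for j in range(m.n_sites)
            if m.sites.at[j, "contig"] == contig and m.sites.at[j, "positioned"]
        ]
        idx.sort(
            key=lambda j: (m.sites.at[j, "pos0"], n_missing[j], m.sites.at[j, "id"])
        )
        last = None
        for j in idx:
            pos = m.sites.at[j, "pos0"]
            if last is not None and abs(pos - last) < dist:
                removed.add(j)
            else:
                last = pos
    return [j not in removed for j in range(m.n_sites)]


def kept_ids(m):
    return list(m.sites["id"])


# ---------------------------------------------------------- unit checks
class TestBoundaries:
    def test_sample_above_90pct_removed(self, rng):
        m = make_matrix(rng, 10, 100, p_missing=0.0)
        m.genotypes[0, :95] = MISSING  # 95% missing
        m.genotypes[1, :90] = MISSING  # exactly 90%
        out = filter_sample_missing(m, 0.90)
        assert m.samples[0] not in out.samples
        assert m.samples[1] in out.samples

    def test_site_at_half_missing_kept(self, rng):
        m = make_matrix(rng, 10, 2, p_missing=0.0)
        m.genotypes[:5, 0] = MISSING  # exactly 50%
        m.genotypes[:6, 1] = MISSING  # 60%
        out = filter_site_missing(m, 0.50)
        assert kept_ids(out) == [m.sites.at[0, "id"]]

    def test_site_missing_zero_threshold(self, rng):
        m = make_matrix(rng, 10, 50, p_missing=0.3)
        out = filter_site_missing(m, 0.0)
        assert (out.genotypes != MISSING).all()

    def test_maf_boundaries(self, rng):
        m = make_matrix(rng, 25, 3, p_missing=0.0)
        m.genotypes[:, 0] = 0
        m.genotypes[0, 0] = 1  # maf 1/50 = 0.02 -> kept (>=)
        m.genotypes[:, 1] = 0  # monomorphic -> removed
        m.genotypes[:, 2] = 0
        m.genotypes[0, 2] = 2  # maf 2/50 = 0.04 -> kept
        out = filter_maf(m, 0.02)
        assert kept_ids(out) == [m.sites.at[0, "id"], m.sites.at[2, "id"]]

    def test_het_boundaries(self, rng):
        m = make_matrix(rng, 100, 3, p_missing=0.0)
        m.genotypes[:, :] = 0
        m.genotypes[0, 0] = 1  # H = 0.01 -> kept at min 0.01
        # site 1: zero hets -> removed
        m.genotypes[:80, 2] = 1  # H = 0.8
        out = filter_het(m, min_het=0.01)
        assert kept_ids(out) == [m.sites.at[0, "id"], m.sites.at[2, "id"]]
        out2 = filter_het(m, min_het=0.01, max_het=0.6)
        assert kept_ids(out2) == [m.sites.at[0, "id"]]

    def test_depth_floor_strict(self, rng):
        m = make_matrix(rng, 4, 2, p_missing=0.0)
        m.depths[:, :] = 7
        m.depths[0, 0] = 5
        out = filter_depth(m, "floor_value", 7)
        assert out.genotypes[0, 0] == MISSING  # 5 < 7
        assert (out.genotypes[1:, :] != MISSING).all()  # exactly 7 retained

    def test_depth_ceiling_strict(self, rng):
        m = make_matrix(rng, 4, 1, p_missing=0.0)
        m.depths[:, 0] = [7, 9, 7, 7]
        out = filter_depth(m, "ceiling_value", 7)
        assert out.genotypes[1, 0] == MISSING
        assert out.genotypes[0, 0] != MISSING

    def test_depth_floor_mean_is_real_valued(self, rng):
        m = make_matrix(rng, 2, 2, p_missing=0.0)
        m.depths[:, :] = [[6, 7], [7, 8]]  # mean 7.0
        out = filter_depth(m, "floor_mean", None)
        assert out.genotypes[0, 0] == MISSING  # 6 < 7.0
        assert (out.genotypes.flatten()[1:] != MISSING).all()

    def test_invariant_examples(self, rng):
        m = make_matrix(rng, 6, 3, p_missing=0.0)
        m.genotypes[:, 0] = 0  # all hom-ref -> removed
        m.genotypes[:, 1] = [0, 0, 0, 2, 2, 2]  # kept
        m.genotypes[:, 2] = 1  # all het: polymorphic -> kept
        out = drop_invariant(m)
        assert kept_ids(out) == list(m.sites["id"][1:])

    def test_prune_spacing_boundaries(self, rng):
        m = make_matrix(rng, 5, 2, p_missing=0.0)
        m.sites["contig"] = "c"
        m.sites["pos0"] = [1000, 1127]  # 127 apart -> second removed
        out, report = prune_linked(m, 128)
        assert kept_ids(out) == [m.sites.at[0, "id"]]
        assert report.at[0, "distance"] == 127
        m.sites["pos0"] = [1000, 1128]  # 128 apart -> both kept
        out2, report2 = prune_linked(m, 128)
        assert out2.n_sites == 2 and report2.empty

    def test_prune_greedy_scan(self, rng):
        m = make_matrix(rng, 5, 3, p_missing=0.0)
        m.sites["contig"] = "c"
        m.sites["pos0"] = [0, 100, 200]
        out, _ = prune_linked(m, 128)
        assert list(out.sites["pos0"]) == [0, 200]

    def test_prune_position_tie_prefers_fewer_missing(self, rng):
        m = make_matrix(rng, 10, 2, p_missing=0.0)
        m.sites["contig"] = "c"
        m.sites["pos0"] = [500, 500]
        m.genotypes[:3, 0] = MISSING
        out, report = prune_linked(m, 128)
        assert kept_ids(out) == [m.sites.at[1, "id"]]
        assert report.at[0, "removed_id"] == m.sites.at[0, "id"]

    def test_unpositioned_sites_pass_with_warning(self, rng):
        m = make_matrix(rng, 5, 10, positioned=False)
        with pytest.warns(UserWarning, match="no positioned sites"):
            out, report = prune_linked(m, 128)
        assert out.n_sites == 10 and report.empty

    def test_all_samples_removed_is_error(self, rng):
        m = make_matrix(rng, 4, 10, p_missing=0.0)
        m.genotypes[:, :] = MISSING
        with pytest.raises(ValueError, match="no samples survive"):
            filter_sample_missing(m, 0.9)


# ------------------------------------------------- oracle equivalence
class TestBruteforceEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_rules_match_oracles(self, seed):
        rng = np.random.default_rng(1000 + seed)
        m = make_matrix(rng, 30, 300)
        thr_miss = rng.choice([0.2, 0.5, 0.8])
        assert kept_ids(filter_site_missing(m, thr_miss)) == [
            i for i, k in zip(m.sites["id"], oracle_site_missing(m, thr_miss)) if k
        ]
        out = filter_sample_missing(m, 0.5)
        assert out.samples == [
            s for s, k in zip(m.samples, oracle_sample_missing(m, 0.5)) if k
        ]
        for thr in (0.02, 0.1):
            assert kept_ids(filter_maf(m, thr)) == [
                i for i, k in zip(m.sites["id"], oracle_maf(m, thr)) if k
            ]
        assert kept_ids(filter_het(m, 0.05, 0.6)) == [
            i for i, k in zip(m.sites["id"], oracle_het(m, 0.05, 0.6)) if k
        ]
        thr_d = float(rng.integers(3, 15))
        keep, masked = oracle_depth_floor(m, thr_d)
        got = filter_depth(m, "floor_value", thr_d)
        assert kept_ids(got) == [
            i for i, k in zip(m.sites["id"], keep) if k
        ]
        assert np.array_equal(
            got.genotypes, masked[:, np.flatnonzero(keep)]
        )
        assert kept_ids(drop_invariant(m)) == [
            i for i, k in zip(m.sites["id"], oracle_invariant(m)) if k
        ]
        assert kept_ids(prune_linked(m, 128)[0]) == [
            i for i, k in zip(m.sites["id"], oracle_prune(m, 128)) if k
        ]


# --------------------------------------------------------- properties
class TestFilterProperties:
    @pytest.mark.parametrize(
        "fn",
        [
            lambda m: filter_site_missing(m, 0.5),
            lambda m: filter_sample_missing(m, 0.7),
            lambda m: filter_maf(m, 0.05),
            lambda m: filter_het(m, 0.02, 0.8),
            lambda m: filter_depth(m, "floor_value", 8),
            lambda m: drop_invariant(m),
            lambda m: prune_linked(m, 128)[0],
        ],
        ids=["site_missing", "sample_missing", "maf", "het", "depth",
             "invariant", "linkage"],
    )
    def test_idempotent(self, rng, fn):
        m = make_matrix(rng, 20, 150)
        once = fn(m)
        twice = fn(once)
        assert once.equals(twice)

    def test_input_never_mutated(self, rng):
        m = make_matrix(rng, 15, 100)
        snapshot = m.copy()
        apply_filters(m, FilterConfig(depth_mode="floor_value", depth_value=6))
        assert m.equals(snapshot)

    def test_maf_het_invariance_under_reorder_and_relabel(self, rng):
        m = make_matrix(rng, 20, 100)
        perm = rng.permutation(20)
        shuffled = m.take_samples(perm)
        assert kept_ids(filter_maf(m, 0.05)) == kept_ids(
            filter_maf(shuffled, 0.05)
        )
        assert kept_ids(filter_het(m, 0.05)) == kept_ids(
            filter_het(shuffled, 0.05)
        )
        flipped = m.copy()  # relabel alleles: dosage 0 <-> 2
        g = flipped.genotypes
        g[g == 0], g[g == 2] = 99, 0  # temp sentinel
        g[g == 99] = 2
        assert kept_ids(filter_maf(m, 0.05)) == kept_ids(
            filter_maf(flipped, 0.05)
        )
        assert kept_ids(filter_het(m, 0.05)) == kept_ids(
            filter_het(flipped, 0.05)
        )

    def test_site_count_monotone_along_chain(self, rng):
        m = make_matrix(rng, 25, 200)
        _, report = apply_filters(
            m, FilterConfig(depth_mode="floor_value", depth_value=5)
        )
        frame = report.to_frame()
        remaining = frame["sites_before"] - frame["sites_removed"]
        assert (frame["sites_before"].to_numpy()[1:]
                == remaining.to_numpy()[:-1]).all()
        assert (frame["sites_removed"] >= 0).all()


class TestApplyFilters:
    def test_identity_config_is_noop(self, rng):
        m = make_matrix(rng, 10, 80)
        out, report = apply_filters(m, IDENTITY_CONFIG)
        assert out.equals(m)
        assert report.to_frame().empty

    def test_unknown_rule_rejected(self, rng):
        m = make_matrix(rng, 10, 50)
        with pytest.raises(ValueError, match="unknown filter rule"):
            apply_filters(m, FilterConfig(), order=["bogus"])

    def test_order_must_be_permutation(self, rng):
        m = make_matrix(rng, 10, 50)
        with pytest.raises(ValueError, match="permutation"):
            apply_filters(m, FilterConfig(), order=["maf"])

    def test_composite_equals_sequential_application(self, rng):
        m = make_matrix(rng, 20, 1000)
        config = FilterConfig(depth_mode="floor_value", depth_value=6)
        out, _ = apply_filters(m, config)
        step = filter_sample_missing(m, config.max_sample_missing)
        step = filter_depth(step, "floor_value", 6)
        step = filter_site_missing(step, config.max_site_missing)
        step = filter_maf(step, config.min_maf)
        step = filter_het(step, config.min_het, config.max_het)
        step = drop_invariant(step)
        step, _ = prune_linked(step, config.min_link_dist)
        assert out.equals(step)

    def test_permuted_order_logged_and_may_differ(self, rng):
        m = make_matrix(rng, 20, 500)
        config = FilterConfig(depth_mode="floor_value", depth_value=10)
        default_out, default_rep = apply_filters(m, config)
        order = ["site_missing", "depth", "sample_missing", "maf", "het",
                 "invariant", "linkage"]
        permuted_out, permuted_rep = apply_filters(m, config, order=order)
        assert list(permuted_rep.to_frame()["rule"]) == order
        assert list(default_rep.to_frame()["rule"]) == [
            r for r in DEFAULT_ORDER
        ]
        # depth-before-missingness differs from missingness-before-depth
        assert permuted_out.n_sites >= default_out.n_sites
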