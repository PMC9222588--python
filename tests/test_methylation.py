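"""Methylation aggregation: parsing, three-way calling, per-site fractions,
consensus, allele stratification, smoothing and method comparison."""

import io

import numpy as np
import pandas as pd
import pytest

from repeatmeth import (
    allele_specific_profiles,
    call_status,
    consensus_profile,
    correlate_methods,
    parse_call_table,
    site_fractions,
    smooth_profile,
)


def records_from(rows):
    """rows: (read_id, position, llr[, caller])"""
    return pd.DataFrame(
        [
            {
                "contig": "locus",
                "position": r[1],
                "read_id": r[0],
                "log_lik_ratio": r[2],
                "caller_id": r[3] if len(r) > 3 else "caller",
            }
            for r in rows
        ]
    )


def site_frame(pairs, stratum="all"):
    """pairs: (position, fraction) -> minimal SiteMethylation frame."""
    return pd.DataFrame(
        {
            "position": [p for p, _ in pairs],
            "methylated_fraction": [f for _, f in pairs],
            "caller_id": "caller",
            "stratum": stratum,
        }
    )


class TestParse:
    def write(self, tmp_path, text, name="calls.tsv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    def test_well_formed(self, tmp_path):
        path = self.write(
            tmp_path,
            "contig\tstrand\tposition\tread_id\tlog_lik_ratio\n"
            "locus\t+\t100\tr1\t3.2\nlocus\t+\t100\tr2\t-4.0\nlocus\t+\t120\tr1\t0.5\n",
        )
        df = parse_call_table(path)
        assert len(df) == 3
        assert set(df.columns) >= {"contig", "position", "read_id", "log_lik_ratio"}

    def test_minus_strand_harmonised_to_plus_c(self, tmp_path):
        path = self.write(
            tmp_path,
            "contig\tstrand\tposition\tread_id\tlog_lik_ratio\n"
            "locus\t-\t101\tr1\t3.0\nlocus\t+\t100\tr2\t3.0\n",
        )
        df = parse_call_table(path)
        assert list(df["position"]) == [100, 100]

    def test_alias_columns_accepted(self, tmp_path):
        path = self.write(
            tmp_path,
            "chromosome\tstart\tread_name\tllr\nlocus\t100\tr1\t3.0\n",
        )
        df = parse_call_table(path, caller_id="x")
        assert df.loc[0, "position"] == 100 and df.loc[0, "caller_id"] == "x"

    def test_missing_column_is_hard_error(self, tmp_path):
        path = self.write(tmp_path, "contig\tposition\tread_id\nlocus\t1\tr1\n")
        with pytest.raises(ValueError, match="log_lik_ratio"):
            parse_call_table(path)

    def test_empty_with_header(self, tmp_path):
        path = self.write(tmp_path, "contig\tstrand\tposition\tread_id\tlog_lik_ratio\n")
        assert parse_call_table(path).empty

    def test_unparseable_ratio_dropped(self, tmp_path):
        path = self.write(
            tmp_path,
            "contig\tstrand\tposition\tread_id\tlog_lik_ratio\n"
            "locus\t+\t100\tr1\tnot_a_number\nlocus\t+\t100\tr2\t2.0\n",
        )
        df = parse_call_table(path)
        assert len(df) == 1 and df.loc[0, "read_id"] == "r2"


class TestCallStatus:
    @pytest.mark.parametrize(
        "llr,expected",
        [(3.0, "methylated"), (-3.0, "unmethylated"), (2.5, "ambiguous"),
         (-2.5, "ambiguous"), (0.0, "ambiguous"), (2.5000001, "methylated")],
    )
    def test_strict_cutoffs(self, llr, expected):
        assert call_status(llr) == expected

    def test_cutoff_must_be_positive(self):
        with pytest.raises(ValueError):
            call_status(1.0, cutoff=0)


class TestSiteFractions:
    def test_confident_fraction(self):
        df = site_fractions(records_from([("a", 10, 6.0), ("b", 10, 4.0), ("c", 10, -6.0)]))
        assert df.loc[0, "methylated_fraction"] == pytest.approx(2 / 3)
        assert df.loc[0, "n_methylated"] == 2 and df.loc[0, "n_unmethylated"] == 1

    def test_all_ambiguous_is_undefined(self):
        df = site_fractions(records_from([("a", 10, 1.0), ("b", 10, -1.0)]))
        assert np.isnan(df.loc[0, "methylated_fraction"])
        assert df.loc[0, "n_ambiguous"] == 2

    def test_ambiguous_excluded_from_both_sides(self):
        df = site_fractions(records_from([("a", 10, 6.0), ("b", 10, -6.0), ("c", 10, 0.0)]))
        assert df.loc[0, "methylated_fraction"] == pytest.approx(0.5)

    def test_binomial_recovery(self):
        """At coverage 100 and p=0.8 the fraction lands in the 95% interval."""
        gen = np.random.default_rng(31)
        states = gen.random(100) < 0.8
        rows = [(f"r{i}", 50, 6.0 if s else -6.0) for i, s in enumerate(states)]
        df = site_fractions(records_from(rows))
        assert df.loc[0, "methylated_fraction"] == pytest.approx(0.8, abs=0.08)


class TestConsensus:
    def test_mean_of_three(self):
        per = {c: site_frame([(10, f)]) for c, f in zip("abc", (0.6, 0.7, 0.8))}
        out = consensus_profile(per)
        assert out.loc[0, "methylated_fraction"] == pytest.approx(0.7)
        assert out.loc[0, "n_callers_defined"] == 3

    def test_undefined_caller_skipped(self):
        per = {
            "a": site_frame([(10, np.nan)]),
            "b": site_frame([(10, 0.5)]),
            "c": site_frame([(10, 0.7)]),
        }
        out = consensus_profile(per)
        assert out.loc[0, "methylated_fraction"] == pytest.approx(0.6)
        assert out.loc[0, "n_callers_defined"] == 2

    def test_single_caller_identity(self):
        per = {"a": site_frame([(10, 0.25), (20, 0.75)])}
        out = consensus_profile(per)
        assert list(out["methylated_fraction"]) == [0.25, 0.75]

    def test_identical_callers_are_identity(self):
        base = site_frame([(10, 0.2), (20, 0.9)])
        out = consensus_profile({"a": base, "b": base.copy(), "c": base.copy()})
        assert np.allclose(out["methylated_fraction"], [0.2, 0.9])

    def test_permutation_invariant(self):
        frames = {c: site_frame([(10, f), (30, 1 - f)]) for c, f in zip("abc", (0.1, 0.5, 0.9))}
        fwd = consensus_profile(frames)
        rev = consensus_profile(dict(reversed(list(frames.items()))))
        pd.testing.assert_frame_equal(fwd, rev)


class TestAlleleSpecific:
    def calls_frame(self, mapping):
        return pd.DataFrame(
            {"read_id": list(mapping), "allele_class": list(mapping.values())}
        )

    def test_full_separation(self):
        records = records_from(
            [("e1", 10, 6.0), ("e2", 10, 5.0), ("n1", 10, -6.0), ("n2", 10, -5.0)]
        )
        calls = self.calls_frame({"e1": "expanded", "e2": "expanded", "n1": "normal", "n2": "normal"})
        strata = allele_specific_profiles(records, calls)
        assert strata["expanded"].loc[0, "methylated_fraction"] == 1.0
        assert strata["normal"].loc[0, "methylated_fraction"] == 0.0
        assert strata["all"].loc[0, "methylated_fraction"] == 0.5

    def test_intermediate_reads_excluded_from_strata(self):
        records = records_from([("i1", 10, 6.0), ("n1", 10, -6.0)])
        calls = self.calls_frame({"i1": "intermediate", "n1": "normal"})
        strata = allele_specific_profiles(records, calls)
        assert strata["normal"].loc[0, "n_unmethylated"] == 1
        assert strata["expanded"].empty
        assert strata["all"].loc[0, "n_methylated"] == 1  # pooled keeps it

    def test_unjoined_reads_only_in_pooled(self):
        records = records_from([("x", 10, 6.0), ("n1", 10, -6.0)])
        calls = self.calls_frame({"n1": "normal"})
        strata = allele_specific_profiles(records, calls)
        assert strata["all"].loc[0, "n_methylated"] == 1
        assert strata["expanded"].empty

    def test_pooled_is_convex_combination_of_strata(self):
        gen = np.random.default_rng(37)
        rows = []
        truth = {}
        for i in range(40):
            rid = f"e{i}"
            truth[rid] = "expanded"
            rows.append((rid, 10, 6.0 if gen.random() < 0.8 else -6.0))
        for i in range(60):
            rid = f"n{i}"
            truth[rid] = "normal"
            rows.append((rid, 10, 6.0 if gen.random() < 0.1 else -6.0))
        strata = allele_specific_profiles(records_from(rows), self.calls_frame(truth))
        fe = strata["expanded"].loc[0, "methylated_fraction"]
        fn = strata["normal"].loc[0, "methylated_fraction"]
        fa = strata["all"].loc[0, "methylated_fraction"]
        ne = strata["expanded"].loc[0, ["n_methylated", "n_unmethylated"]].sum()
        nn = strata["normal"].loc[0, ["n_methylated", "n_unmethylated"]].sum()
        assert fa == pytest.approx((ne * fe + nn * fn) / (ne + nn))
        assert min(fn, fe) < fa < max(fn, fe)

    def test_stratified_counts_never_exceed_pooled(self):
        records = records_from(
            [("e1", 10, 6.0), ("n1", 10, 6.0), ("i1", 10, 6.0), ("x", 10, 6.0)]
        )
        calls = self.calls_frame({"e1": "expanded", "n1": "normal", "i1": "intermediate"})
        strata = allele_specific_profiles(records, calls)
        strat_sum = sum(
            int(strata[s].loc[0, "n_methylated"]) for s in ("normal", "expanded") if not strata[s].empty
        )
        assert strat_sum <= int(strata["all"].loc[0, "n_methylated"])


def tricube_wls_oracle(x, y, span):
    """Direct weighted-least-squares lowess oracle per evaluation point."""
    n = len(x)
    k = int(np.ceil(span * n))
    out = np.empty(n)
    for i, x0 in enumerate(x):
        d = np.abs(x - x0)
        h = np.sort(d)[k - 1]
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3 if h > 0 else (d == 0).astype(float)
        W = np.diag(w)
        X = np.column_stack([np.ones(n), x - x0])
        beta = np.linalg.pinv(X.T @ W @ X) @ X.T @ W @ y
        out[i] = beta[0]
    return out


class TestSmoothing:
    def test_constant_preserved(self):
        sites = site_frame([(p, 0.5) for p in range(0, 100, 10)])
        out = smooth_profile(sites)
        assert np.allclose(out["smoothed_fraction"], 0.5)

    def test_linear_reproduced_in_interior(self):
        x = np.arange(0, 40)
        sites = site_frame(list(zip(x, 0.2 + 0.01 * x)))
        out = smooth_profile(sites, bandwidth=0.5)
        interior = slice(10, 30)
        expected = (0.2 + 0.01 * x)[interior]
        assert np.allclose(out["smoothed_fraction"].to_numpy()[interior], expected, atol=1e-6)

    def test_step_matches_wls_oracle_and_stays_in_range(self):
        x = np.arange(0, 60, dtype=float)
        y = np.where(x < 30, 0.1, 0.9)
        sites = site_frame(list(zip(x.astype(int), y)))
        out = smooth_profile(sites, bandwidth=0.4)
        got = out["smoothed_fraction"].to_numpy()
        expected = np.clip(tricube_wls_oracle(x, y, 0.4), 0, 1)
        assert np.allclose(got, expected, atol=1e-8)
        assert got.min() >= 0.1 - 1e-9 and got.max() <= 0.9 + 1e-9
        assert np.all(np.diff(got) >= -1e-9)  # monotone transition

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            smooth_profile(site_frame([(1, 0.5)]))


class TestCorrelation:
    def test_identical_profiles(self):
        gen = np.random.default_rng(41)
        vals = gen.random(10)
        a = site_frame(list(zip(range(10), vals)))
        b = site_frame(list(zip(range(10), vals)))
        cmp_ = correlate_methods(a, b)
        assert cmp_.pearson_r == pytest.approx(1.0)
        assert cmp_.n_overlapping_sites == 10

    def test_anticorrelated(self):
        gen = np.random.default_rng(43)
        vals = gen.random(10)
        a = site_frame(list(zip(range(10), vals)))
        b = site_frame(list(zip(range(10), 1 - vals)))
        assert correlate_methods(a, b).pearson_r == pytest.approx(-1.0)

    def test_null_distribution_at_n50(self):
        """Independent uniforms at 50 sites: |r| < 0.4 in >=95% of replicates."""
        gen = np.random.default_rng(47)
        small = 0
        for _ in range(200):
            a = site_frame(list(zip(range(50), gen.random(50))))
            b = site_frame(list(zip(range(50), gen.random(50))))
            if abs(correlate_methods(a, b).pearson_r) < 0.4:
                small += 1
        assert small / 200 >= 0.95

    def test_too_few_overlaps(self):
        a = site_frame([(1, 0.5), (2, 0.6)])
        b = site_frame([(3, 0.5), (4, 0.6)])
        with pytest.raises(ValueError):
            correlate_methods(a, b)
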