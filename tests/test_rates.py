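import io

import numpy as np
import pandas as pd
import pytest

from phylorates import (BranchRatesTable, branch_is_valid, parse_newick,
                        read_rates_tsv, root_to_tip_omega, root_to_tip_path,
                        simulate_tree, write_rates_tsv)
from phylorates.errors import RatesTableError


def make_table(rows):
    return BranchRatesTable(pd.DataFrame(
        rows, columns=["gene", "branch", "dN", "dS", "omega"]))


class TestBranchIsValid:
    @pytest.mark.parametrize("dn,ds,expected", [
        (0.01, 0.02, True),
        (0.0001, 0.02, False),       # outlier rule applied to dN
        (0.02, 0.0001, False),       # and to dS
        (0.0002, 0.0002, True),      # "less than" is strict: boundary passes
    ])
    def test_rule(self, dn, ds, expected):
        assert branch_is_valid(dn, ds) is expected

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            branch_is_valid(-0.1, 0.2)


class TestRootToTipOmega:
    def test_hand_average(self, small_tree):
        t = make_table([("g", "N1", 0.01, 0.05, 0.2), ("g", "A", 0.02, 0.05, 0.4),
                        ("g", "B", 0.01, 0.05, 0.2), ("g", "C", 0.01, 0.05, 0.2)])
        out = root_to_tip_omega(small_tree, t).set_index("species")
        assert out.loc["A", "omega_bar"] == pytest.approx(0.3)
        assert out.loc["A", "log10_omega_bar"] == pytest.approx(np.log10(0.3))
        assert out.loc["A", "n_valid_branches"] == 2

    def test_outlier_branch_excluded(self, small_tree):
        # the extreme ω=5 branch has sub-threshold dS and must not contaminate
        tree = parse_newick("(((A:1,B:1):1,D:2):1,C:3);")
        t = make_table([("g", "N1", 0.01, 0.05, 0.2), ("g", "N2", 0.02, 0.05, 0.4),
                        ("g", "A", 0.0005, 0.0001, 5.0), ("g", "B", 0.01, 0.05, 0.2),
                        ("g", "D", 0.01, 0.05, 0.2), ("g", "C", 0.01, 0.05, 0.2)])
        out = root_to_tip_omega(tree, t).set_index("species")
        assert out.loc["A", "omega_bar"] == pytest.approx(0.3)

    def test_all_invalid_gives_na(self, small_tree):
        t = make_table([("g", "N1", 0.0001, 0.05, 0.002),
                        ("g", "A", 0.0001, 0.05, 0.002),
                        ("g", "B", 0.01, 0.05, 0.2), ("g", "C", 0.01, 0.05, 0.2)])
        out = root_to_tip_omega(small_tree, t).set_index("species")
        assert np.isnan(out.loc["A", "omega_bar"])
        assert out.loc["A", "n_valid_branches"] == 0

    def test_unknown_branch_raises(self, small_tree):
        t = make_table([("g", "BOGUS", 0.01, 0.05, 0.2)])
        with pytest.raises(RatesTableError, match="BOGUS"):
            root_to_tip_omega(small_tree, t)

    def test_threshold_monotonicity(self, rng):
        """Raising the validity threshold never increases n_valid_branches."""
        tree = simulate_tree(8, seed=1)
        branches = [n for n in tree.parent if tree.parent[n] is not None]
        df = pd.DataFrame({
            "gene": "g", "branch": branches,
            "dN": rng.uniform(0, 0.002, len(branches)),
            "dS": rng.uniform(0, 0.002, len(branches)),
        })
        df["omega"] = df["dN"] / df["dS"].replace(0, np.nan)
        t = BranchRatesTable(df)
        prev = None
        for thr in [0.0001, 0.0002, 0.0005, 0.001, 0.002]:
            n = root_to_tip_omega(tree, t, threshold=thr)["n_valid_branches"]
            if prev is not None:
                assert (n <= prev).all()
            prev = n

    def test_row_order_invariance(self, small_tree, rng):
        t = make_table([("g", b, 0.01, 0.05, w) for b, w in
                        [("N1", 0.1), ("A", 0.2), ("B", 0.3), ("C", 0.4)]])
        shuffled = BranchRatesTable(
            t.df.sample(frac=1, random_state=7).reset_index(drop=True))
        a = root_to_tip_omega(small_tree, t)
        b = root_to_tip_omega(small_tree, shuffled)
        pd.testing.assert_frame_equal(
            a.sort_values(["gene", "species"]).reset_index(drop=True),
            b.sort_values(["gene", "species"]).reset_index(drop=True))

    def test_matches_naive_path_oracle(self):
        """Independent oracle: enumerate every root-to-tip path naively and
        average valid ω by hand, over random trees and random tables."""
        rng = np.random.default_rng(123)
        for seed in range(50):
            tree = simulate_tree(6, seed=seed)
            branches = [n for n in tree.parent if tree.parent[n] is not None]
            df = pd.DataFrame({
                "gene": "g", "branch": branches,
                "dN": rng.uniform(0, 0.01, len(branches)),
                "dS": rng.uniform(0, 0.01, len(branches)),
            })
            df["omega"] = np.where(df["dS"] > 0, df["dN"] / df["dS"], np.nan)
            out = root_to_tip_omega(tree, BranchRatesTable(df)).set_index("species")
            lookup = df.set_index("branch")
            for tip in tree.tips:
                vals = []
                node = tip
                while tree.parent[node] is not None:
                    rec = lookup.loc[node]
                    if rec["dN"] >= 0.0002 and rec["dS"] >= 0.0002:
                        vals.append(rec["omega"])
                    node = tree.parent[node]
                if vals:
                    assert out.loc[tip, "omega_bar"] == pytest.approx(
                        float(np.mean(vals)), abs=1e-12)
                else:
                    assert np.isnan(out.loc[tip, "omega_bar"])

    def test_ratio_of_sums_alternative(self, small_tree):
        t = make_table([("g", "N1", 0.01, 0.05, 0.2), ("g", "A", 0.03, 0.05, 0.6),
                        ("g", "B", 0.01, 0.05, 0.2), ("g", "C", 0.01, 0.05, 0.2)])
        out = root_to_tip_omega(small_tree, t, method="ratio_of_sums")
        a = out.set_index("species").loc["A", "omega_bar"]
        assert a == pytest.approx(0.04 / 0.10)


class TestRatesIO:
    TSV = ("gene\tbranch\tdN\tdS\tomega\n"
           "g1\tA\t0.01\t0.05\t0.2\n" "g1\tB\t0.02\t0.05\t0.4\n"
           "g1\tN1\t0.01\t0.05\t0.2\n" "g1\tC\t0.01\t0.05\t0.2\n"
           "g2\tA\t0.01\t0.05\t0.2\n" "g2\tB\t0.02\t0.05\t0.4\n"
           "g2\tN1\t0.01\t0.05\t0.2\n" "g2\tC\t0.01\t0.05\t0.2\n")

    def test_read_fixture(self, tmp_path):
        p = tmp_path / "rates.tsv"
        p.write_text(self.TSV)
        table = read_rates_tsv(p)
        assert len(table.df) == 8
        assert table.genes == ["g1", "g2"]

    def test_round_trip_identity(self, tmp_path):
        p = tmp_path / "rates.tsv"
        p.write_text(self.TSV)
        table = read_rates_tsv(p)
        q = tmp_path / "out.tsv"
        write_rates_tsv(table, q)
        pd.testing.assert_frame_equal(read_rates_tsv(q).df, table.df)

    def test_omega_recomputed_and_zero_ds(self, tmp_path):
        p = tmp_path / "rates.tsv"
        p.write_text("gene\tbranch\tdN\tdS\n" "g\tA\t0.01\t0.05\n" "g\tB\t0.01\t0\n")
        table = read_rates_tsv(p)
        df = table.df.set_index("branch")
        assert df.loc["A", "omega"] == pytest.approx(0.2)
        assert np.isnan(df.loc["B", "omega"])
        assert not branch_is_valid(0.01, 0.0)

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "rates.tsv"
        p.write_text("gene\tbranch\tdN\n" "g\tA\t0.01\n")
        with pytest.raises(RatesTableError, match="dS"):
            read_rates_tsv(p)

    def test_non_numeric_raises(self, tmp_path):
        p = tmp_path / "rates.tsv"
        p.write_text("gene\tbranch\tdN\tdS\n" "g\tA\tx\t0.05\n")
        with pytest.raises(RatesTableError):
            read_rates_tsv(p)

    def test_duplicate_rows_raise(self):
        with pytest.raises(RatesTableError, match="duplicate"):
            make_table([("g", "A", 0.01, 0.05, 0.2), ("g", "A", 0.01, 0.05, 0.2)])
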