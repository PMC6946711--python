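import itertools

import numpy as np
import pandas as pd
import pytest

from mycoassembly.datamodel import (
    CommunityTable,
    SampleMetadata,
    TableMode,
    TaxonAnnotation,
    patristic_distances,
    taxonomy_to_cladogram,
)
from mycoassembly.nullmodels import (
    NullModelResult,
    beta_mntd,
    bnti,
    classify_processes,
    raup_crick,
    stochastic_fraction,
    within_group_pairs,
)


def table_from(rows, taxa=None, mode=TableMode.counts):
    rows = np.asarray(rows, dtype=float)
    taxa = taxa or [f"t{j}" for j in range(rows.shape[1])]
    df = pd.DataFrame(rows, index=[f"s{i}" for i in range(rows.shape[0])], columns=taxa)
    return CommunityTable(df, mode)


def annotation_for(paths):
    """Build a TaxonAnnotation from taxon_id -> (phylum..genus) tuples."""
    rows = []
    for tid, (p, c, o, f, g) in paths.items():
        rows.append(
            {
                "taxon_id": tid,
                "kingdom": "Fungi",
                "phylum": p,
                "class": c,
                "order": o,
                "family": f,
                "genus": g,
                "guild": "saprotroph",
            }
        )
    return TaxonAnnotation(pd.DataFrame(rows))


@pytest.fixture
def four_tip_tree():
    annot = annotation_for(
        {
            "t0": ("p1", "c1", "o1", "f1", "g1"),
            "t1": ("p1", "c1", "o1", "f1", "g1"),
            "t2": ("p1", "c1", "o1", "f1", "g2"),
            "t3": ("p2", "c2", "o2", "f2", "g3"),
        }
    )
    return taxonomy_to_cladogram(annot)


@pytest.fixture
def star_tree():
    annot = annotation_for(
        {f"t{i}": ("p1", "c1", "o1", "f1", "g1") for i in range(4)}
    )
    return taxonomy_to_cladogram(annot)


def brute_bmntd(D, xa, xb, weighted=True):
    """Independent betaMNTD: plain loops over present taxa."""
    ia = [i for i, v in enumerate(xa) if v > 0]
    ib = [j for j, v in enumerate(xb) if v > 0]
    wa = np.array([xa[i] for i in ia], dtype=float)
    wb = np.array([xb[j] for j in ib], dtype=float)
    wa, wb = wa / wa.sum(), wb / wb.sum()
    da = [min(D[i][j] for j in ib) for i in ia]
    db = [min(D[i][j] for i in ia) for j in ib]
    if weighted:
        return 0.5 * (np.dot(wa, da) + np.dot(wb, db))
    return 0.5 * (np.mean(da) + np.mean(db))


class TestBetaMNTD:
    def test_single_shared_taxon_zero(self, four_tip_tree):
        tab = table_from([[5, 0, 0, 0], [3, 0, 0, 0]])
        dm = beta_mntd(tab, four_tip_tree)
        assert dm["s0", "s1"] == 0.0

    def test_two_singletons_equal_patristic(self, four_tip_tree):
        tab = table_from([[1, 0, 0, 0], [0, 0, 1, 0]])
        dm = beta_mntd(tab, four_tip_tree)
        D = patristic_distances(four_tip_tree, tab.taxon_ids)
        assert dm["s0", "s1"] == pytest.approx(D["t0", "t2"])

    def test_equal_abundances_match_unweighted(self, four_tip_tree):
        tab = table_from([[1, 1, 0, 0], [0, 0, 1, 1]])
        w = beta_mntd(tab, four_tip_tree, weighted=True)
        u = beta_mntd(tab, four_tip_tree, weighted=False)
        np.testing.assert_allclose(w.data, u.data, atol=1e-12)

    def test_matches_brute_force(self, four_tip_tree, rng):
        tab = table_from(rng.integers(0, 5, size=(4, 4)) + np.eye(4))
        D = patristic_distances(four_tip_tree, tab.taxon_ids).data
        dm = beta_mntd(tab, four_tip_tree)
        for i, j in itertools.combinations(range(4), 2):
            expected = brute_bmntd(D, tab.values[i], tab.values[j])
            assert dm.data[i, j] == pytest.approx(expected)

    def test_missing_taxon_named(self, four_tip_tree):
        tab = table_from([[1, 1, 1, 1, 1]], taxa=["t0", "t1", "t2", "t3", "ghost"])
        with pytest.raises(Exception, match="ghost"):
            beta_mntd(tab, four_tip_tree)


class TestBNTI:
    def test_star_tree_degenerate(self, star_tree):
        tab = table_from([[1, 1, 0, 0], [0, 0, 1, 1]])
        res = bnti(tab, star_tree, reps=49, seed=0)
        assert res.degenerate.all()
        assert np.isnan(res.score).all()

    def test_matches_exhaustive_tip_permutations(self, four_tip_tree):
        """Monte-Carlo z-score agrees with complete enumeration of all 4!
        tip relabelings within Monte-Carlo error."""
        tab = table_from([[2, 1, 0, 0], [0, 0, 1, 3]])
        D = patristic_distances(four_tip_tree, tab.taxon_ids).data
        obs = brute_bmntd(D, tab.values[0], tab.values[1])
        null = []
        for perm in itertools.permutations(range(4)):
            Dp = D[np.ix_(perm, perm)]
            null.append(brute_bmntd(Dp, tab.values[0], tab.values[1]))
        null = np.array(null)
        z_exact = (obs - null.mean()) / null.std(ddof=0)
        reps = 999
        res = bnti(tab, four_tip_tree, reps=reps, seed=1)
        se = np.sqrt((1 + z_exact**2 / 2) / reps)
        assert res.score[0] == pytest.approx(z_exact, abs=3 * se)

    def test_invariant_to_branch_length_scale(self, four_tip_tree):
        annot = annotation_for(
            {
                "t0": ("p1", "c1", "o1", "f1", "g1"),
                "t1": ("p1", "c1", "o1", "f1", "g1"),
                "t2": ("p1", "c1", "o1", "f1", "g2"),
                "t3": ("p2", "c2", "o2", "f2", "g3"),
            }
        )
        scaled_tree = taxonomy_to_cladogram(annot, branch_length_per_rank=3.5)
        tab = table_from([[2, 1, 0, 0], [0, 0, 1, 3], [1, 0, 2, 0]])
        a = bnti(tab, four_tip_tree, reps=99, seed=7)
        b = bnti(tab, scaled_tree, reps=99, seed=7)
        np.testing.assert_allclose(a.score, b.score, atol=1e-10)

    def test_reps_validated(self, four_tip_tree):
        tab = table_from([[1, 0, 0, 0], [0, 1, 0, 0]])
        with pytest.raises(ValueError):
            bnti(tab, four_tip_tree, reps=0)


def exact_rci_presence(X, i, j, reps_dist=None):
    """Exact Raup-Crick by complete enumeration of occupancy-weighted
    richness-preserving draws for both samples of a pair."""
    pres = X > 0
    occ = pres.sum(axis=0).astype(float)
    S = X.shape[1]

    def subset_probs(k):
        probs = {}
        for order in itertools.permutations(range(S), k):
            if any(occ[t] == 0 for t in order):
                continue
            p = 1.0
            remaining = occ.sum()
            for t in order:
                p *= occ[t] / remaining
                remaining -= occ[t]
            key = frozenset(order)
            probs[key] = probs.get(key, 0.0) + p
        return probs

    pa = subset_probs(int(pres[i].sum()))
    pb = subset_probs(int(pres[j].sum()))
    obs = int(np.count_nonzero(pres[i] & pres[j]))
    p_more = p_tie = 0.0
    for sa, qa in pa.items():
        for sb, qb in pb.items():
            shared = len(sa & sb)
            if shared > obs:
                p_more += qa * qb
            elif shared == obs:
                p_tie += qa * qb
    return 2.0 * (p_more + 0.5 * p_tie) - 1.0


class TestRaupCrick:
    def test_identical_pair_hits_lower_bound(self):
        """A pair sharing a full, rare presence set is more similar than
        essentially every richness-preserving null draw."""
        rows = [[1, 1, 1, 1] + [0] * 26, [1, 1, 1, 1] + [0] * 26]
        for k in range(12):  # background occupancy spread over 30 taxa
            row = [0] * 30
            row[k % 30] = 1
            row[(k + 7) % 30] = 1
            row[(k + 14) % 30] = 1
            row[(k + 21) % 30] = 1
            rows.append(row)
        tab = table_from(rows)
        res = raup_crick(tab, reps=499, seed=3, pairs=[("s0", "s1")])
        assert res.score[0] == pytest.approx(-1.0, abs=0.02)

    def test_disjoint_pair_in_tight_pool_near_upper_bound(self):
        """Two disjoint samples drawn over a pool where nulls almost always
        overlap sit near RCI = +1."""
        rows = [
            [1, 1, 1, 0, 0, 0],
            [0, 0, 0, 1, 1, 1],
        ] + [[1, 1, 1, 1, 1, 1]] * 20
        tab = table_from(rows)
        res = raup_crick(tab, reps=999, seed=3, pairs=[("s0", "s1")])
        assert res.score[0] > 0.9

    def test_monte_carlo_matches_exact_enumeration(self):
        """Monte-Carlo RCI within 0.1 of the exactly enumerated value."""
        X = np.array(
            [
                [3, 1, 0, 0],
                [0, 2, 2, 0],
                [1, 0, 0, 4],
                [0, 1, 1, 0],
            ],
            dtype=float,
        )
        tab = table_from(X)
        for (i, j) in [(0, 1), (0, 2), (1, 3)]:
            exact = exact_rci_presence(X, i, j)
            res = raup_crick(tab, reps=999, seed=11, pairs=[(f"s{i}", f"s{j}")])
            assert res.score[0] == pytest.approx(exact, abs=0.1)

    def test_taxon_relabeling_invariance(self, rng):
        X = rng.integers(0, 4, size=(6, 12)).astype(float)
        X[(X > 0).sum(axis=1) == 0, 0] = 1
        tab = table_from(X)
        perm = rng.permutation(12)
        tab_perm = table_from(X[:, perm], taxa=[f"t{j}" for j in perm])
        a = raup_crick(tab, reps=999, seed=5, pairs=[("s0", "s1")])
        b = raup_crick(tab_perm, reps=999, seed=6, pairs=[("s0", "s1")])
        assert a.score[0] == pytest.approx(b.score[0], abs=0.15)

    def test_zero_richness_rejected(self):
        with pytest.raises(ValueError):
            raup_crick(table_from([[0, 0], [1, 1]]))

    def test_abundance_variant_runs_and_bounds(self, rng):
        X = rng.integers(0, 6, size=(5, 10)).astype(float)
        X[(X > 0).sum(axis=1) == 0, 0] = 1
        res = raup_crick(table_from(X), reps=99, variant="abundance_bray", seed=0)
        assert ((res.score >= -1) & (res.score <= 1)).all()


def make_result(kind, pairs, scores, degenerate=None):
    n = len(pairs)
    scores = np.asarray(scores, dtype=float)
    return NullModelResult(
        pairs=pairs,
        observed=np.zeros(n),
        null_mean=np.zeros(n),
        null_sd=np.ones(n),
        reps=999,
        score=scores,
        degenerate=np.zeros(n, bool) if degenerate is None else np.asarray(degenerate),
        kind=kind,
    )


class TestClassification:
    @pytest.mark.parametrize(
        "bn, rc, expected",
        [
            (-3.0, -1.0, "homogeneous_selection"),
            (0.5, 0.2, "stochastic_undominated"),
            (1.0, -0.99, "selection_or_dispersal_ambiguous"),
            (2.5, 0.0, "variable_selection"),
            (0.0, 0.97, "dispersal_limitation"),
        ],
    )
    def test_threshold_scheme(self, bn, rc, expected):
        pairs = [("a", "b")]
        table, summary = classify_processes(
            make_result("bnti", pairs, [bn]), make_result("rci", pairs, [rc])
        )
        assert table["process"].iloc[0] == expected
        assert summary.fractions[expected] == 1.0

    def test_degenerate_bnti_classified_on_rci(self):
        pairs = [("a", "b")]
        table, _ = classify_processes(
            make_result("bnti", pairs, [np.nan], degenerate=[True]),
            make_result("rci", pairs, [-0.99]),
        )
        assert table["process"].iloc[0] == "selection_or_dispersal_ambiguous"

    def test_mismatched_pairs_rejected(self):
        with pytest.raises(ValueError):
            classify_processes(
                make_result("bnti", [("a", "b")], [0.0]),
                make_result("rci", [("a", "c")], [0.0]),
            )

    def test_fractions_sum_to_one(self, rng):
        pairs = [(f"a{i}", f"b{i}") for i in range(40)]
        table, summary = classify_processes(
            make_result("bnti", pairs, rng.normal(0, 2, 40)),
            make_result("rci", pairs, rng.uniform(-1, 1, 40)),
        )
        assert sum(summary.fractions.values()) == pytest.approx(1.0)


class TestStochasticFraction:
    @pytest.fixture
    def metadata(self):
        return SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": ["a1", "a2", "a3", "b1", "b2", "lone"],
                    "compartment": ["leaf"] * 3 + ["root"] * 2 + ["soil"],
                    "week": [1] * 6,
                    "treatment": ["control"] * 6,
                }
            )
        )

    def test_counts_within_groups(self, metadata):
        pair_table = pd.DataFrame(
            {
                "sample_a": ["a1", "a1", "a2", "b1", "a1"],
                "sample_b": ["a2", "a3", "a3", "b2", "b1"],
                "process": [
                    "stochastic_undominated",
                    "stochastic_undominated",
                    "homogeneous_selection",
                    "dispersal_limitation",
                    "stochastic_undominated",  # cross-group pair, ignored
                ],
            }
        )
        out = stochastic_fraction(pair_table, metadata, ["compartment"])
        leaf = out[out["compartment"] == "leaf"].iloc[0]
        root = out[out["compartment"] == "root"].iloc[0]
        assert leaf["stochastic_fraction"] == pytest.approx(2 / 3)
        assert leaf["n_pairs"] == 3
        assert root["stochastic_fraction"] == 0.0
        assert "soil" not in set(out["compartment"])

    def test_within_group_pairs_helper(self, metadata):
        pairs = within_group_pairs(metadata, ["compartment"])
        assert ("a1", "a2") in pairs and ("b1", "b2") in pairs
        assert all(a[0] == b[0] for a, b in pairs)  # never cross-compartment


class TestDispersalRegimeRecovery:
    """The two dispersal regimes leave opposite Raup-Crick signatures."""

    def test_homogenizing_dispersal_drives_rci_to_lower_bound(self):
        """Migrant exchange keeps replicates sharing more taxa than the
        occupancy null expects, so RCI approaches -1."""
        from mycoassembly.synthetic import (
            AssemblyScenario,
            sample_metacommunity,
            simulate_assembly,
        )

        meta = sample_metacommunity(S=200, lognormal_sigma=1.0, seed=1)
        drift = simulate_assembly(
            meta,
            AssemblyScenario(process="drift", N=100, generations=20, m=0.1, seed=1),
            12,
            sample_ids=[f"drift_{k}" for k in range(12)],
        )
        hd = simulate_assembly(
            meta,
            AssemblyScenario(
                process="homogenizing_dispersal", N=200, generations=20, m=0.5, seed=3
            ),
            12,
            sample_ids=[f"hd_{k}" for k in range(12)],
        )
        big = CommunityTable(pd.concat([drift.data, hd.data]), TableMode.counts)
        ids = big.sample_ids
        pairs = [
            (ids[12 + i], ids[12 + j]) for i in range(12) for j in range(i + 1, 12)
        ]
        res = raup_crick(big, reps=299, seed=1, pairs=pairs)
        assert np.mean(res.score <= -0.95) >= 0.9

    def test_dispersal_limitation_elevates_rci_over_drift(self):
        """Against a backdrop of well-mixed communities (which set the
        occupancy expectation), dispersal-limited replicates share fewer
        taxa than the null predicts, pushing RCI upward."""
        from mycoassembly.synthetic import (
            AssemblyScenario,
            sample_metacommunity,
            simulate_assembly,
        )

        meta = sample_metacommunity(S=200, lognormal_sigma=1.0, seed=1)
        mixed = simulate_assembly(
            meta,
            AssemblyScenario(process="drift", N=100, generations=20, m=0.3, seed=1),
            24,
            sample_ids=[f"mixed_{k}" for k in range(24)],
        )
        limited = simulate_assembly(
            meta,
            AssemblyScenario(
                process="dispersal_limitation",
                N=500,
                generations=2,
                seeding_fraction=0.25,
                seed=2,
            ),
            12,
            sample_ids=[f"lim_{k}" for k in range(12)],
        )
        big = CommunityTable(
            pd.concat([mixed.data, limited.data]), TableMode.counts
        )
        ids = big.sample_ids
        pairs = []
        for group in (ids[:24], ids[24:]):
            pairs += [
                (group[i], group[j])
                for i in range(len(group))
                for j in range(i + 1, len(group))
            ]
        res = raup_crick(big, reps=499, seed=5, pairs=pairs)
        n_mixed = 24 * 23 // 2
        drift_scores = res.score[:n_mixed]
        limited_scores = res.score[n_mixed:]
        assert np.mean(limited_scores >= 0.95) >= np.mean(drift_scores >= 0.95)
        assert limited_scores.mean() > drift_scores.mean() + 0.5
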