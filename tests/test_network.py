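"""Filter cascade, network assembly, pairwise overlap report."""

import numpy as np
import pandas as pd
import pytest

from are_regnet.io import read_sif, write_sif
from are_regnet.metrics import DependencyResult
from are_regnet.network import (
    TargetFilterConfig,
    build_network,
    filter_targets,
    pairwise_overlap_report,
    selected_targets,
)


def _dep(records: dict) -> DependencyResult:
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "gene"
    return DependencyResult(regulator="REG", scores=df)


@pytest.fixture
def dep():
    # three genes pass everything; the rest each fail exactly one filter
    return _dep(
        {
            "BCL2": {"mic": 0.9, "lr_slope": -1.2, "q": 0.001},
            "BNIP2": {"mic": 0.8, "lr_slope": -0.8, "q": 0.002},
            "OPA1": {"mic": 0.7, "lr_slope": -0.5, "q": 0.005},
            "HIGHQ": {"mic": 0.6, "lr_slope": -1.0, "q": 0.5},
            "NOARE": {"mic": 0.85, "lr_slope": -1.0, "q": 0.001},
            "POSLR": {"mic": 0.75, "lr_slope": 0.9, "q": 0.001},
            "NOANN": {"mic": 0.65, "lr_slope": -0.4, "q": 0.001},
        }
    )


@pytest.fixture
def hitsets():
    return {
        "BCL2": 2, "BNIP2": 3, "OPA1": 2, "HIGHQ": 2, "POSLR": 2, "NOANN": 2,
        # NOARE absent: treated as zero copies
    }


@pytest.fixture
def annotation():
    return {g: {"apoptosis"} for g in ("BCL2", "BNIP2", "OPA1", "HIGHQ", "NOARE", "POSLR")}


class TestFilterTargets:
    def test_exactly_the_planted_targets_survive(self, dep, hitsets, annotation):
        cfg = TargetFilterConfig(annotation_terms=frozenset({"apoptosis"}))
        prov = filter_targets(dep, hitsets, annotation, cfg)
        assert selected_targets(prov) == ["BCL2", "BNIP2", "OPA1"]

    def test_each_filter_recorded_in_provenance(self, dep, hitsets, annotation):
        cfg = TargetFilterConfig(annotation_terms=frozenset({"apoptosis"}))
        prov = filter_targets(dep, hitsets, annotation, cfg)
        assert not prov.loc["HIGHQ", "pass_q"]
        assert not prov.loc["NOARE", "pass_are"]
        assert not prov.loc["POSLR", "pass_lr"]
        assert not prov.loc["NOANN", "pass_annotation"]
        assert prov["selected"].equals(
            prov[["pass_q", "pass_are", "pass_lr", "pass_annotation"]].all(axis=1)
        )

    def test_dropping_lr_filter_gives_superset(self, dep, hitsets, annotation):
        on = TargetFilterConfig(require_negative_lr=True)
        off = TargetFilterConfig(require_negative_lr=False)
        s_on = set(selected_targets(filter_targets(dep, hitsets, annotation, on)))
        s_off = set(selected_targets(filter_targets(dep, hitsets, annotation, off)))
        assert s_on <= s_off
        assert "POSLR" in s_off - s_on

    def test_empty_annotation_terms_skips_filter(self, dep, hitsets):
        cfg = TargetFilterConfig()  # no terms configured
        prov = filter_targets(dep, hitsets, None, cfg)
        assert prov["pass_annotation"].all()
        assert "NOANN" in selected_targets(prov)

    def test_missing_q_column_rejected(self, hitsets):
        bare = _dep({"A": {"mic": 0.5, "lr_slope": -1.0}})
        with pytest.raises(ValueError, match="q column"):
            filter_targets(bare, hitsets, None, TargetFilterConfig())


class TestBuildNetwork:
    def test_shared_targets_have_in_degree_two(self):
        shared = ["BCL2", "BNIP2", "OPA1"]
        net = build_network(
            {"ZFP36": shared + ["UNIQ1"], "ZFP36L1": shared + ["UNIQ2"]}
        )
        for g in shared:
            assert net.in_degree(g) == 2
        assert net.in_degree("UNIQ1") == 1

    def test_single_regulator_edge_count_no_self_edge(self):
        net = build_network({"REG": ["T1", "T2", "T3", "REG"]})
        assert net.number_of_edges() == 3
        assert not any(u == v for u, v in net.edges())

    def test_provenance_table_input_and_sif_round_trip(self, dep, hitsets, annotation, tmp_path):
        cfg = TargetFilterConfig(annotation_terms=frozenset({"apoptosis"}))
        prov = filter_targets(dep, hitsets, annotation, cfg)
        net = build_network({"REG": prov})
        assert set(net.successors("REG")) == {"BCL2", "BNIP2", "OPA1"}
        assert net.edges["REG", "BCL2"]["q"] == pytest.approx(0.001)
        p = tmp_path / "net.sif"
        write_sif(net, p)
        assert set(read_sif(p).edges()) == set(net.edges())


class TestPairwiseOverlap:
    def test_identical_sets_small_universe(self):
        universe = [f"G{i}" for i in range(10)]
        s = set(universe[:5])
        report = pairwise_overlap_report({"A": s, "B": set(s)}, universe)
        assert report[("A", "B")].p_value == pytest.approx(1 / 252, rel=1e-12)

    def test_disjoint_sets_p_one(self):
        universe = [f"G{i}" for i in range(10)]
        report = pairwise_overlap_report(
            {"A": set(universe[:3]), "B": set(universe[5:8])}, universe
        )
        assert report[("A", "B")].p_value == pytest.approx(1.0)

    def test_symmetric_in_pair_order(self):
        universe = [f"G{i}" for i in range(20)]
        rng = np.random.default_rng(0)
        sa = set(rng.choice(universe, 6, replace=False))
        sb = set(rng.choice(universe, 8, replace=False))
        r1 = pairwise_overlap_report({"A": sa, "B": sb}, universe)[("A", "B")]
        r2 = pairwise_overlap_report({"A": sb, "B": sa}, universe)[("A", "B")]
        assert r1.p_value == r2.p_value

    def test_needs_two_regulators(self):
        with pytest.raises(ValueError, match="two regulators"):
            pairwise_overlap_report({"A": {"G1"}}, ["G1"])
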