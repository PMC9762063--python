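import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pathbn.cgbn import NetworkStructure
from pathbn.fragment import (
    FragmentGraph,
    annotate_fragment,
    extract_fragment,
    fragment_to_dot,
    fragment_to_frame,
    jackknife_mi,
    _mi_gaussian,
)
from pathbn.stability import ArcConfidenceTable, AveragedNetwork


def _net(arcs, nodes=None, conf=None, threshold=0.6):
    nodes = nodes or sorted({x for a in arcs for x in a})
    conf = conf or {a: 0.9 for a in arcs}
    return AveragedNetwork(structure=NetworkStructure(nodes, arcs),
                           confidence=conf, threshold=threshold)


class TestExtractFragment:
    def test_unreachable_branch_excluded(self):
        net = _net([("I", "X"), ("X", "PA2"), ("I", "PA2"), ("Z", "PA2")])
        frag = extract_fragment(net, "I", {"PA2"})
        assert frag.arcs == frozenset({("I", "X"), ("X", "PA2"), ("I", "PA2")})
        assert "Z" not in frag.structure.nodes

    def test_no_path_gives_empty_fragment(self):
        net = _net([("X", "PA2")], nodes=["I", "X", "PA2"])
        frag = extract_fragment(net, "I", {"PA2"})
        assert frag.arcs == frozenset()

    def test_source_in_targets_rejected(self):
        net = _net([("I", "PA2")])
        with pytest.raises(ValueError):
            extract_fragment(net, "I", {"I", "PA2"})

    def test_matches_simple_path_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(40):
            n = int(rng.integers(4, 10))
            nodes = [f"v{i}" for i in range(n)]
            arcs = [(nodes[i], nodes[j]) for i in range(n) for j in range(i + 1, n)
                    if rng.random() < 0.35]
            net = _net(arcs, nodes=nodes)
            targets = set(rng.choice(nodes[1:], size=2, replace=False))
            frag = extract_fragment(net, nodes[0], targets)
            g = net.structure.to_networkx()
            oracle = set()
            for t in targets:
                for path in nx.all_simple_paths(g, nodes[0], t):
                    oracle.update(zip(path[:-1], path[1:]))
            assert frag.arcs == frozenset(oracle)

    def test_idempotent(self):
        net = _net([("I", "X"), ("X", "PA2"), ("I", "PA2")])
        frag = extract_fragment(net, "I", {"PA2"})
        again = extract_fragment(
            AveragedNetwork(frag.structure, frag.confidence, net.threshold),
            "I", {"PA2"})
        assert again.arcs == frag.arcs

    def test_threshold_monotone(self):
        arcs = [("I", "X"), ("X", "PA2"), ("I", "PA2")]
        conf = {("I", "X"): 0.65, ("X", "PA2"): 0.75, ("I", "PA2"): 0.95}
        net = _net(arcs, conf=conf)
        low = extract_fragment(net, "I", {"PA2"}, 0.6)
        high = extract_fragment(net, "I", {"PA2"}, 0.7)
        assert high.arcs <= low.arcs
        assert ("I", "X") not in high.arcs


class TestJackknifeMI:
    def test_independent_normals_near_zero(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(2000), rng.standard_normal(2000)
        assert jackknife_mi(x, y) < 0.01

    def test_gaussian_oracle_rho_06(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(2000)
        y = 0.6 * x + math.sqrt(1 - 0.36) * rng.standard_normal(2000)
        assert jackknife_mi(x, y) == pytest.approx(-0.5 * math.log(1 - 0.36), abs=0.02)

    def test_perfect_discrete_dependence_gives_entropy(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 500)
        assert jackknife_mi(x, x.copy()) == pytest.approx(math.log(2), abs=0.02)

    def test_symmetric_and_non_negative(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        y = 0.3 * x + rng.standard_normal(200)
        assert jackknife_mi(x, y) == pytest.approx(jackknife_mi(y, x), abs=1e-9)
        assert jackknife_mi(x, rng.standard_normal(200)) >= 0.0

    def test_pairwise_complete_cases_used(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(500)
        y = 0.8 * x + 0.6 * rng.standard_normal(500)
        x2, y2 = x.copy(), y.copy()
        x2[:40] = np.nan
        y2[460:] = np.nan
        full = jackknife_mi(x[40:460], y[40:460])
        assert jackknife_mi(x2, y2) == pytest.approx(full, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            jackknife_mi([1.0] * 5 + [np.nan] * 10, list(range(15)))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            jackknife_mi([1.0] * 50, list(np.arange(50.0)))

    def test_correction_reduces_small_sample_bias(self):
        # moderate correlation keeps the Monte-Carlo error of the bias
        # estimate well below the plug-in bias it is compared against
        rho, true = 0.3, -0.5 * math.log(1 - 0.09)
        corrected, plug = [], []
        for s in range(200):
            rng = np.random.default_rng(s)
            x = rng.standard_normal(50)
            y = rho * x + math.sqrt(1 - rho ** 2) * rng.standard_normal(50)
            corrected.append(jackknife_mi(x, y))
            plug.append(_mi_gaussian(x, y))
        assert abs(np.mean(corrected) - true) <= abs(np.mean(plug) - true)


class TestAnnotate:
    def _fragment_with_mi(self, mis, confs):
        arcs = [("I", f"X{i}") for i in range(len(mis))]
        nodes = ["I"] + [f"X{i}" for i in range(len(mis))]
        frag = FragmentGraph(
            structure=NetworkStructure(nodes, arcs), source="I",
            targets=(nodes[-1],), stability_threshold=0.6,
            confidence={a: c for a, c in zip(arcs, confs)})
        frag.mi = {a: m for a, m in zip(arcs, mis)}
        return frag, arcs

    def test_band_assignment_from_quantiles_and_cutoffs(self):
        # three arcs with MI strictly between the 33%/67% cut-offs
        rng = np.random.default_rng(6)
        n = 400
        cols = {"I": rng.standard_normal(n)}
        for i, rho in enumerate((0.3, 0.6, 0.85)):
            cols[f"X{i}"] = rho * cols["I"] + math.sqrt(1 - rho ** 2) * \
                rng.standard_normal(n)
        data = pd.DataFrame(cols)
        arcs = [("I", "X0"), ("I", "X1"), ("I", "X2")]
        frag = FragmentGraph(structure=NetworkStructure(list(cols), arcs),
                             source="I", targets=("X2",), stability_threshold=0.6,
                             confidence={arcs[0]: 0.65, arcs[1]: 0.85, arcs[2]: 0.95})
        conf = ArcConfidenceTable(counts={}, n_boot=1)
        out = annotate_fragment(frag, data, conf)
        assert [out.mi_band[a] for a in arcs] == [1, 2, 3]
        assert [out.width_band[a] for a in arcs] == [1, 3, 4]
        assert out.mi_cutoffs is not None and out.mi_range is not None
        lo, hi = out.mi_range
        assert lo <= out.mi_cutoffs[0] <= out.mi_cutoffs[1] <= hi

    def test_width_bands_at_published_cutoffs(self):
        confs = [0.65, 0.75, 0.85, 0.95]
        rng = np.random.default_rng(7)
        n = 300
        cols = {"I": rng.standard_normal(n)}
        for i in range(4):
            cols[f"X{i}"] = 0.5 * cols["I"] + rng.standard_normal(n)
        arcs = [("I", f"X{i}") for i in range(4)]
        frag = FragmentGraph(structure=NetworkStructure(list(cols), arcs),
                             source="I", targets=("X3",), stability_threshold=0.6,
                             confidence=dict(zip(arcs, confs)))
        out = annotate_fragment(frag, pd.DataFrame(cols),
                                ArcConfidenceTable(counts={}, n_boot=1))
        assert [out.width_band[a] for a in arcs] == [1, 2, 3, 4]
        assert all(a in out.mi_band for a in arcs)

    def test_exports_cover_every_arc(self):
        rng = np.random.default_rng(8)
        n = 200
        cols = {"I": rng.standard_normal(n)}
        cols["X0"] = 0.5 * cols["I"] + rng.standard_normal(n)
        arcs = [("I", "X0")]
        frag = FragmentGraph(structure=NetworkStructure(["I", "X0"], arcs),
                             source="I", targets=("X0",), stability_threshold=0.6,
                             confidence={arcs[0]: 0.8})
        out = annotate_fragment(frag, pd.DataFrame(cols),
                                ArcConfidenceTable(counts={}, n_boot=1))
        frame = fragment_to_frame(out)
        assert len(frame) == 1
        assert {"confidence", "mi", "mi_band", "width_band"} <= set(frame.columns)
        dot = fragment_to_dot(out)
        assert '"I" -> "X0"' in dot and "penwidth" in dot
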