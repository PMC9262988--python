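"""Six-frame translation, ortholog top-hit assignment, parsimony pathways."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

import coreprof as cp
from coreprof.functional import OrthologReference, _greedy_cover

# simple codon table for back-translating peptides in fixtures
BACK = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}


def back_translate(pep):
    return "".join(BACK[a] for a in pep)


def random_peptide(rng, n):
    return "".join(rng.choice(list(BACK)) for _ in range(n))


@pytest.fixture(scope="module")
def ortho_ref():
    rng = np.random.default_rng(42)
    peptides = {f"K{i:05d}": random_peptide(rng, 60) for i in range(1, 9)}
    return OrthologReference(peptides, k_aa=5)


class TestSixFrame:
    def test_known_codon_translation(self):
        assert cp.six_frame_translate("ATGGCC")[0] == "MA"

    def test_always_six_frames(self, rng):
        for n in (3, 10, 33, 150):
            read = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            assert len(cp.six_frame_translate(read)) == 6

    def test_reverse_frames_equal_forward_of_revcomp(self, rng):
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 90))
        rc = str(Seq(read).reverse_complement())
        assert cp.six_frame_translate(read)[3:] == cp.six_frame_translate(rc)[:3]

    def test_ambiguous_base_becomes_x(self):
        assert cp.six_frame_translate("ATGNNN")[0] == "MX"


def oracle_score(read, reference):
    """Exhaustive shared-k-mer count oracle, one score per ortholog."""
    k = reference.k_aa
    scores = {}
    for ko, pep in reference.peptides.items():
        kmers = {pep[i : i + k] for i in range(len(pep) - k + 1)}
        s = 0
        for frame in cp.six_frame_translate(read):
            for i in range(len(frame) - k + 1):
                if frame[i : i + k] in kmers:
                    s += 1
        if s:
            scores[ko] = s
    return scores


class TestAssignOrtholog:
    def test_back_translated_fragment_assigned(self, ortho_ref):
        pep = ortho_ref.peptides["K00003"]
        read = back_translate(pep[10:40])
        assert cp.assign_ortholog(read, ortho_ref) == "K00003"

    def test_random_decoy_unassigned(self, ortho_ref, rng):
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
        assert cp.assign_ortholog(read, ortho_ref) is None

    def test_top_hit_matches_exhaustive_count_oracle(self, ortho_ref, rng):
        for ko in list(ortho_ref.peptides)[:4]:
            pep = ortho_ref.peptides[ko]
            read = back_translate(pep[:30]) + "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
            scores = oracle_score(read, ortho_ref)
            got = cp.assign_ortholog(read, ortho_ref)
            if not scores:
                assert got is None
            else:
                top = max(scores.values())
                winners = [k for k, v in scores.items() if v == top]
                assert got == (winners[0] if len(winners) == 1 else None)

    def test_exact_tie_is_unassigned(self):
        ref = OrthologReference({"K1": "MKTAYIAKQR", "K2": "MKTAYIAKQR"}, k_aa=5)
        read = back_translate("MKTAYIAKQR")
        assert cp.assign_ortholog(read, ref) is None

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            OrthologReference({})

    def test_assignment_recall_on_exact_fragments(self, ortho_ref, rng):
        # error-free reads drawn from reference orthologs: recall >= 0.9
        hits = total = 0
        for _ in range(10):
            for ko, pep in ortho_ref.peptides.items():
                start = int(rng.integers(0, len(pep) - 30))
                read = back_translate(pep[start : start + 30])
                total += 1
                hits += cp.assign_ortholog(read, ortho_ref) == ko
        assert hits / total >= 0.9


def oracle_min_cover(universe, pathway_map):
    """Exhaustive minimum over all pathway subsets."""
    names = sorted(pathway_map)
    best = None
    for r in range(len(names) + 1):
        for combo in itertools.combinations(names, r):
            cov = set().union(*(pathway_map[p] for p in combo)) if combo else set()
            if universe <= cov:
                return set(combo)
    return best


class TestInferPathways:
    def test_single_pathway_covers_all(self):
        pmap = {"P1": {"K1", "K2", "K3"}, "P2": {"K9"}}
        inf = cp.infer_pathways(["K1", "K3"], pmap)
        assert inf.pathways == frozenset({"P1"})
        assert inf.exact

    def test_matches_exhaustive_subset_oracle(self, rng):
        # random 6-pathway / 10-ortholog maps: result size equals the true
        # minimum over all 2^6 subsets
        orthologs = [f"K{i}" for i in range(10)]
        for trial in range(25):
            pmap = {
                f"P{j}": set(rng.choice(orthologs, size=rng.integers(1, 6), replace=False))
                for j in range(6)
            }
            observed = set(rng.choice(orthologs, size=rng.integers(1, 8), replace=False))
            coverable = {k for k in observed if any(k in m for m in pmap.values())}
            inf = cp.infer_pathways(observed, pmap)
            expected = oracle_min_cover(coverable, pmap)
            assert len(inf.pathways) == len(expected)
            got_cov = set().union(*(pmap[p] for p in inf.pathways)) if inf.pathways else set()
            assert coverable <= got_cov

    def test_orthologs_in_no_pathway_dropped(self):
        pmap = {"P1": {"K1"}}
        with pytest.warns(UserWarning, match="no pathway"):
            inf = cp.infer_pathways(["K9"], pmap)
        assert inf.pathways == frozenset()
        assert inf.dropped_orthologs == frozenset({"K9"})

    def test_empty_observation_empty_result(self):
        inf = cp.infer_pathways([], {"P1": {"K1"}})
        assert inf.pathways == frozenset()

    def test_greedy_flagged_and_near_optimal(self, rng):
        # >20 pathways: greedy mode; size within +2 of the exact optimum
        # computed on an equivalent reduced instance
        orthologs = [f"K{i}" for i in range(12)]
        pmap = {
            f"P{j}": set(rng.choice(orthologs, size=rng.integers(1, 5), replace=False))
            for j in range(24)
        }
        observed = orthologs
        inf = cp.infer_pathways(observed, pmap)
        assert not inf.exact
        exact = oracle_min_cover(
            {k for k in observed if any(k in m for m in pmap.values())}, pmap
        )
        assert len(inf.pathways) <= len(exact) + 2

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError, match="no member"):
            cp.infer_pathways(["K1"], {"P1": set()})


class TestPathwayAbundance:
    def test_sum_of_member_counts(self):
        counts = pd.Series({"K1": 3, "K2": 4})
        out = cp.pathway_abundance(counts, ["P1"], {"P1": {"K1", "K2"}})
        assert out["P1"] == 7

    def test_shared_ortholog_counts_in_both(self):
        counts = pd.Series({"K1": 5})
        pmap = {"P1": {"K1"}, "P2": {"K1", "K2"}}
        out = cp.pathway_abundance(counts, ["P1", "P2"], pmap)
        assert out["P1"] == 5 and out["P2"] == 5

    def test_matches_direct_summation_oracle(self, rng):
        orthologs = [f"K{i}" for i in range(15)]
        for _ in range(20):
            counts = pd.Series(rng.integers(0, 20, len(orthologs)), index=orthologs)
            pmap = {
                f"P{j}": set(rng.choice(orthologs, size=rng.integers(1, 7), replace=False))
                for j in range(5)
            }
            kept = [p for p in pmap if rng.random() < 0.7]
            out = cp.pathway_abundance(counts, kept, pmap)
            for p in kept:
                assert out[p] == sum(counts[k] for k in pmap[p])


class TestEndToEndFunctional:
    def test_reads_to_pathway_table(self, ortho_ref, rng):
        reads = [back_translate(ortho_ref.peptides["K00001"][5:45])] * 3
        reads += [back_translate(ortho_ref.peptides["K00002"][0:40])] * 2
        counts = cp.count_orthologs(reads, ortho_ref, sample_id="s1")
        assert counts["K00001"] == 3 and counts["K00002"] == 2
        pmap = {"PA": {"K00001", "K00002"}, "PB": {"K00001"}}
        inf = cp.infer_pathways(counts.index, pmap)
        assert inf.pathways == frozenset({"PA"})
        ab = cp.pathway_abundance(counts, inf.pathways, pmap)
        assert ab["PA"] == 5
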