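"""Classification rules, circularity, mini-CRISPR, similarity, demarcation."""

import numpy as np
import pandas as pd
import pytest

from spacerlink.classification import (
    ScaffoldFeatures,
    classify,
    demarcate,
    detect_circularity,
    detect_mini_crispr,
    features_from_inputs,
    intergenomic_similarity,
    similarity_matrix,
)
from spacerlink.sequtils import random_dna


class TestDetectCircularity:
    def test_terminal_repeat_detected(self, rng):
        core = random_dna(rng, 9945)
        seq = core + core[:55]
        assert detect_circularity(seq) == (True, 55, 9945)

    def test_random_sequence_linear(self, rng):
        seq = random_dna(rng, 10_000)
        assert detect_circularity(seq) == (False, 0, 10_000)

    def test_too_short_sequence(self, rng):
        seq = random_dna(rng, 30)
        assert detect_circularity(seq) == (False, 0, 30)

    def test_rotation_invariance(self, rng):
        """Regenerating the terminal-repeat convention from any rotation of
        the underlying circle is still detected as circular."""
        core = random_dna(rng, 5000)
        for shift in (0, 1, 1234, 4999):
            rotated = core[shift:] + core[:shift]
            seq = rotated + rotated[:55]
            circ, k, trimmed = detect_circularity(seq)
            assert circ and k == 55 and trimmed == 5000


class TestDetectMiniCrispr:
    def _planted(self, rng, n_spacers, repeat_len=29):
        repeat = random_dna(rng, repeat_len)
        parts = [random_dna(rng, 300), repeat]
        for _ in range(n_spacers):
            parts.append(random_dna(rng, 33))
            parts.append(repeat)
        parts.append(random_dna(rng, 300))
        return "".join(parts), repeat

    def test_single_spacer_mini_array(self, rng):
        seq, repeat = self._planted(rng, 1)
        arrays = detect_mini_crispr(seq)
        assert len(arrays) == 1
        assert arrays[0].n_spacers == 1
        assert repeat in arrays[0].repeat or arrays[0].repeat in repeat + repeat

    def test_extensive_thirty_spacer_array(self, rng):
        seq, _ = self._planted(rng, 30)
        arrays = detect_mini_crispr(seq)
        assert len(arrays) == 1
        assert arrays[0].n_spacers == 30

    def test_random_sequence_has_no_arrays(self, rng):
        assert detect_mini_crispr(random_dna(rng, 20_000)) == []


class TestClassify:
    def test_length_gate(self):
        f = ScaffoldFeatures("s", length=2900, spacer_targeted=True)
        assert classify(f).verdict == "not_considered"

    def test_circular_with_hallmarks_is_virus(self):
        f = ScaffoldFeatures(
            "s", length=20_000, is_circular=True, hallmark_gene_count=2,
            vog_hit_count=3, spacer_targeted=True,
        )
        c = classify(f)
        assert c.verdict == "virus"
        assert "circular" in c.reasons

    def test_linear_targeted_without_hallmarks_is_putative(self):
        f = ScaffoldFeatures("s", length=10_000, spacer_targeted=True)
        assert classify(f).verdict == "putative_virus"

    def test_extensive_crispr_array_rejected(self):
        f = ScaffoldFeatures(
            "s", length=50_000, crispr_array_spacer_count=30, spacer_targeted=True
        )
        c = classify(f)
        assert c.verdict == "rejected"
        assert c.reasons == ["extensive_crispr_array"]

    def test_bacterial_hits_without_hallmarks_rejected(self):
        f = ScaffoldFeatures(
            "s", length=30_000, bacterial_hit_count=5, spacer_targeted=True
        )
        assert classify(f).verdict == "rejected"

    def test_mini_array_does_not_reject(self):
        f = ScaffoldFeatures(
            "s", length=10_000, crispr_array_spacer_count=1, spacer_targeted=True
        )
        assert classify(f).verdict == "putative_virus"

    def test_total_function_over_feature_grid(self):
        """Every feature combination yields exactly one non-empty verdict."""
        verdicts = {"virus", "putative_virus", "rejected", "not_considered"}
        for length in (1000, 5000):
            for circ in (False, True):
                for hall in (0, 2):
                    for bact in (0, 5):
                        for crispr in (0, 1, 8):
                            for targeted in (False, True):
                                c = classify(
                                    ScaffoldFeatures(
                                        "s", length, circ, 0, hall, hall, bact,
                                        crispr, targeted,
                                    )
                                )
                                assert c.verdict in verdicts
                                assert c.reasons

    def test_features_from_inputs_wires_annotations(self, rng):
        core = random_dna(rng, 6000)
        scaffolds = [("v1", core + core[:55]), ("v2", random_dna(rng, 5000))]
        ann = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "scaffold_id": ["v1", "v2"],
                "is_hallmark": [1, 0],
                "is_vog_hit": [1, 0],
                "is_bacterial": [0, 1],
            }
        )
        feats = {f.scaffold_id: f for f in features_from_inputs(scaffolds, ann, {"v1"})}
        assert feats["v1"].is_circular and feats["v1"].hallmark_gene_count == 1
        assert feats["v1"].spacer_targeted
        assert feats["v2"].bacterial_hit_count == 1 and not feats["v2"].spacer_targeted


class TestIntergenomicSimilarity:
    def test_identical_genomes(self, rng):
        g = random_dna(rng, 10_000)
        assert intergenomic_similarity(g, g) == 100.0

    def test_unrelated_genomes_score_zero(self, rng):
        a, b = random_dna(rng, 10_000), random_dna(rng, 10_000)
        assert intergenomic_similarity(a, b) == 0.0

    def test_five_percent_divergence(self, rng):
        """5% random substitutions give ~95% similarity (+/- 1.5)."""
        a = random_dna(rng, 10_000)
        b = list(a)
        for p in np.flatnonzero(rng.random(10_000) < 0.05):
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        sim = intergenomic_similarity(a, "".join(b))
        assert sim == pytest.approx(95.0, abs=1.5)

    def test_symmetry(self, rng):
        a = random_dna(rng, 5_000)
        b = a[:2500] + random_dna(rng, 2500)
        assert intergenomic_similarity(a, b) == pytest.approx(
            intergenomic_similarity(b, a)
        )

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            intergenomic_similarity("", "ACGT")


class TestDemarcate:
    def _matrix(self, sims: dict[tuple[str, str], float], ids):
        m = pd.DataFrame(100.0 * np.eye(len(ids)), index=ids, columns=ids)
        for (a, b), v in sims.items():
            m.loc[a, b] = v
            m.loc[b, a] = v
        return m

    def test_single_genome(self):
        sp, gen = demarcate(self._matrix({}, ["A"]))
        assert sp == {"A": 0} and gen == {"A": 0}

    def test_worked_single_linkage_example(self):
        m = self._matrix({("A", "B"): 96, ("A", "C"): 50, ("B", "C"): 50},
                         ["A", "B", "C"])
        species, genera = demarcate(m)
        assert species["A"] == species["B"] != species["C"]
        assert genera["A"] == genera["B"] == genera["C"]

    def test_all_below_genus_threshold(self):
        m = self._matrix({("A", "B"): 5, ("A", "C"): 10, ("B", "C"): 2},
                         ["A", "B", "C"])
        _, genera = demarcate(m)
        assert len(set(genera.values())) == 3

    def test_asymmetric_matrix_rejected(self):
        m = pd.DataFrame([[100.0, 50.0], [60.0, 100.0]], index=["A", "B"],
                         columns=["A", "B"])
        with pytest.raises(ValueError, match="symmetric"):
            demarcate(m)

    def test_species_refine_genera_on_random_matrices(self, rng):
        """Single-linkage monotonicity: species clusters nest in genus clusters."""
        for _ in range(20):
            n = 6
            vals = rng.uniform(0, 100, size=(n, n))
            sym = (vals + vals.T) / 2
            np.fill_diagonal(sym, 100.0)
            ids = [f"g{i}" for i in range(n)]
            m = pd.DataFrame(sym, index=ids, columns=ids)
            species, genera = demarcate(m)
            for a in ids:
                for b in ids:
                    if species[a] == species[b]:
                        assert genera[a] == genera[b]

    def test_similarity_matrix_roundtrip(self, rng):
        g1 = random_dna(rng, 4000)
        g2 = list(g1)
        for p in np.flatnonzero(rng.random(4000) < 0.03):
            g2[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[g2[p]]
        genomes = [("a", g1), ("b", "".join(g2)), ("c", random_dna(rng, 4000))]
        m = similarity_matrix(genomes)
        species, genera = demarcate(m)
        assert species["a"] == species["b"]  # ~97% similar: one species
        assert genera["c"] not in (genera["a"],)
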