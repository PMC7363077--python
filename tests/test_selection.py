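"""Nei-Gojobori site counting, coding-effect calls, hN/hS behaviour."""

import numpy as np
import pandas as pd
import pytest

from mtduplex.mtgenome import revcomp, translate_codon
from mtduplex.selection import (
    classify_coding_mutation,
    hn_hs,
    ng_sites,
    ng_sites_genome,
)

ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


def brute_force_sites(cds):
    """Independent oracle: enumerate every codon x position x alt."""
    syn = non = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aa = translate_codon(codon)
        if aa == "*":
            continue
        for j in range(3):
            for alt in "ACGT":
                if alt == codon[j]:
                    continue
                mut = codon[:j] + alt + codon[j + 1 :]
                if translate_codon(mut) == aa:
                    syn += 1 / 3
                else:
                    non += 1 / 3
    return non, syn


class TestNgSites:
    def test_phenylalanine_codon_worked_example(self):
        # TTT: only TTC is synonymous (Phe); 1 of 9 changes -> 1/3 site
        counts = ng_sites("TTT")
        assert counts.synonymous == pytest.approx(1 / 3)
        assert counts.nonsynonymous == pytest.approx(8 / 3)

    @pytest.mark.parametrize("codon", ALL_CODONS)
    def test_every_codon_contributes_three_sites(self, codon):
        counts = ng_sites(codon)
        expected = 0.0 if translate_codon(codon) == "*" else 3.0
        assert counts.total == pytest.approx(expected)

    def test_whole_gene_matches_brute_force_oracle(self, genome):
        gene = next(f for f in genome.features if f.kind == "protein-coding")
        cds = genome.cds_sequence(gene)
        counts = ng_sites(cds)
        non, syn = brute_force_sites(cds)
        assert counts.nonsynonymous == pytest.approx(non)
        assert counts.synonymous == pytest.approx(syn)

    def test_length_not_divisible_by_three_rejected(self):
        with pytest.raises(ValueError):
            ng_sites("ACGTA")

    def test_genome_totals_sum_over_genes(self, genome):
        total = ng_sites_genome(genome)
        per_gene = [
            ng_sites(genome.cds_sequence(f))
            for f in genome.features
            if f.kind == "protein-coding"
        ]
        assert total.nonsynonymous == pytest.approx(sum(c.nonsynonymous for c in per_gene))
        assert total.synonymous == pytest.approx(sum(c.synonymous for c in per_gene))


class TestCodingEffect:
    @staticmethod
    def find_effect(genome, wanted, strand=None):
        for f in genome.features:
            if f.kind != "protein-coding" or (strand and f.strand != strand):
                continue
            for pos in range(f.start, f.end + 1):
                if genome.compartment_of(pos) != "protein-coding":
                    continue
                for alt in "ACGT":
                    if alt == genome.base(pos):
                        continue
                    if classify_coding_mutation(genome, pos, alt) == wanted:
                        return f, pos, alt
        return None

    def test_synonymous_and_stop_gained_exist_on_both_strands(self, genome):
        for strand in ("L", "H"):
            assert self.find_effect(genome, "synonymous", strand) is not None
            assert self.find_effect(genome, "stop_gained", strand) is not None

    def test_start_codon_disruption_is_start_lost(self, genome):
        gene = next(
            f for f in genome.features if f.kind == "protein-coding" and f.strand == "L"
        )
        # ATG -> CTG is not a mitochondrial start codon
        assert genome.sequence[gene.start - 1 : gene.start + 2] == "ATG"
        assert classify_coding_mutation(genome, gene.start, "C") == "start_lost"

    def test_h_strand_codon_read_on_coding_strand(self, genome):
        gene = next(
            f for f in genome.features if f.kind == "protein-coding" and f.strand == "H"
        )
        # the reference holds the reverse complement: the CDS start codon
        # sits at the feature end
        assert revcomp(genome.sequence[gene.end - 3 : gene.end]) == "ATG"
        # reference G at the feature end is the complement of the CDS's
        # leading A; changing it to ref C reads as coding A>C: ATG -> CTG,
        # which cannot initiate
        assert classify_coding_mutation(genome, gene.end, "G") == "start_lost"
        # coding A>G gives GTG, still a valid mitochondrial start codon
        assert classify_coding_mutation(genome, gene.end, "C") != "start_lost"

    def test_noncoding_position_rejected(self, genome):
        dloop = next(f for f in genome.features if f.kind == "D-loop")
        with pytest.raises(ValueError):
            classify_coding_mutation(genome, dloop.start, "A")


class TestHnHs:
    @staticmethod
    def mutations_at(genome, effects, wanted):
        rows = []
        for f in genome.features:
            if f.kind != "protein-coding":
                continue
            for pos in range(f.start, f.end + 1):
                if genome.compartment_of(pos) != "protein-coding":
                    continue
                ref = genome.base(pos)
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    eff = classify_coding_mutation(genome, pos, alt)
                    key = "nonsynonymous" if eff != "synonymous" else "synonymous"
                    if key == wanted:
                        rows.append({"position": pos, "ref": ref, "alt": alt})
                        if len(rows) >= effects:
                            return pd.DataFrame(rows)
        return pd.DataFrame(rows)

    def test_all_synonymous_gives_zero_ratio(self, genome, rng):
        muts = self.mutations_at(genome, 30, "synonymous")
        res = hn_hs(muts, genome, n_boot=50, rng=rng)
        assert res.hn == 0.0
        assert res.ratio == 0.0

    def test_all_nonsynonymous_gives_undefined_ratio(self, genome, rng):
        muts = self.mutations_at(genome, 30, "nonsynonymous")
        res = hn_hs(muts, genome, n_boot=50, rng=rng)
        assert res.hs == 0.0
        assert res.ratio is None
        assert res.p_value is None

    def test_input_order_invariance(self, genome):
        muts = pd.concat(
            [
                self.mutations_at(genome, 15, "synonymous"),
                self.mutations_at(genome, 15, "nonsynonymous"),
            ],
            ignore_index=True,
        )
        r1 = hn_hs(muts, genome, n_boot=40, rng=np.random.default_rng(1))
        r2 = hn_hs(
            muts.sample(frac=1.0, random_state=3).reset_index(drop=True),
            genome,
            n_boot=40,
            rng=np.random.default_rng(1),
        )
        assert r1.ratio == pytest.approx(r2.ratio)
        assert np.allclose(r1.null_ratios, r2.null_ratios)

    def test_uniform_neutral_placement_mean_ratio_near_one(self, genome, rng):
        """With every substitution equally likely (uniform spectrum), the
        Nei-Gojobori site normalisation makes the expected ratio 1; a
        biased spectrum shifts the neutral expectation, which is why the
        significance test bootstraps its null from the spectrum."""
        from mtduplex.selection import _nonsyn_lookup
        from mtduplex.simulate import MUTATION_TYPES

        positions, impact = _nonsyn_lookup(genome)
        # weight each type by its base opportunity -> every (site, alt)
        # substitution is equally likely
        type_w = np.array([positions[t[0]].size for t in MUTATION_TYPES], dtype=float)
        type_w /= type_w.sum()
        ratios = []
        for _ in range(60):
            rows = []
            for ti in rng.choice(len(MUTATION_TYPES), size=400, p=type_w):
                t = MUTATION_TYPES[ti]
                pos = int(positions[t[0]][rng.integers(positions[t[0]].size)])
                rows.append({"position": pos, "ref": t[0], "alt": t[2]})
            res = hn_hs(pd.DataFrame(rows), genome, n_boot=10, rng=rng)
            ratios.append(res.ratio)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.06)

    def test_transition_biased_spectrum_shifts_neutral_ratio_below_one(self, genome, rng):
        # transitions preferentially hit synonymous third positions
        from mtduplex.selection import _nonsyn_lookup
        from mtduplex.simulate import DEFAULT_SPECTRUM, MUTATION_TYPES

        positions, _ = _nonsyn_lookup(genome)
        type_w = np.array(
            [DEFAULT_SPECTRUM[t] * positions[t[0]].size for t in MUTATION_TYPES]
        )
        type_w /= type_w.sum()
        rows = []
        for ti in rng.choice(len(MUTATION_TYPES), size=2000, p=type_w):
            t = MUTATION_TYPES[ti]
            pos = int(positions[t[0]][rng.integers(positions[t[0]].size)])
            rows.append({"position": pos, "ref": t[0], "alt": t[2]})
        res = hn_hs(pd.DataFrame(rows), genome, n_boot=100, rng=rng)
        assert res.ratio < 0.85
        # and yet the spectrum-matched bootstrap does NOT reject it
        assert res.p_value > 0.05
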