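"""Synthetic-data generators: determinism, truth encoding, length law."""

import numpy as np
import pytest

from srnapipe import synthdata
from srnapipe.errors import ParameterError
from srnapipe.preprocess import CleanParams, clean, collapse, modal_length
from srnapipe.targets import revcomp, score_duplex


class TestMakeReference:
    def test_sizes_and_family_structure(self):
        ref = synthdata.make_reference(seed=1, n_mirna=50, n_families=40)
        assert len(ref.mature_mirnas) == 50
        from srnapipe.annotate import assign_family

        families = {assign_family(m.id) for m in ref.mature_mirnas}
        assert len(families) == 40

    def test_seeded_determinism(self):
        a = synthdata.make_reference(seed=1, n_mirna=50, n_families=40)
        b = synthdata.make_reference(seed=1, n_mirna=50, n_families=40)
        assert [(m.id, m.seq) for m in a.mature_mirnas] == [
            (m.id, m.seq) for m in b.mature_mirnas
        ]
        assert [t.seq for t in a.transcripts] == [t.seq for t in b.transcripts]

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ParameterError):
            synthdata.make_reference(seed=1, n_families=0)
        with pytest.raises(ParameterError):
            synthdata.make_reference(seed=1, n_mirna=5, n_families=10)

    def test_planted_sites_have_intended_scores(self, reference):
        for planted in reference.planted_sites:
            mir = next(m for m in reference.mature_mirnas if m.id == planted.mirna_id)
            tx = next(t for t in reference.transcripts if t.id == planted.transcript_id)
            site = tx.seq[planted.start - 1 : planted.end]
            assert score_duplex(mir.seq, site).score == planted.intended_score
        scores = {p.intended_score for p in reference.planted_sites}
        assert 0.0 in scores and any(s > 0 for s in scores)


class TestSimulateLibrary:
    def test_depth_zero_rejected(self, reference, truth):
        with pytest.raises(ParameterError):
            synthdata.simulate_library(reference, 0, truth, "CK", seed=1)

    def test_deterministic_for_seed(self, reference, truth):
        a, _ = synthdata.simulate_library(reference, 2000, truth, "CK", seed=5)
        b, _ = synthdata.simulate_library(reference, 2000, truth, "CK", seed=5)
        assert [(r.id, r.seq, r.qual) for r in a] == [(r.id, r.seq, r.qual) for r in b]

    def test_modal_insert_length_is_24(self, reference, truth):
        reads, _ = synthdata.simulate_library(reference, 30000, truth, "CK", seed=2)
        cleaned, _ = clean(reads, CleanParams(adapter=reference.adapter))
        assert modal_length(collapse({"CK": cleaned})) == 24

    def test_membership_truth_matches_counts(self, reference, truth):
        _, t = synthdata.simulate_library(reference, 20000, truth, "A", seed=3)
        counts = t.realized_counts["A"]
        assert t.membership["A"] == {m for m, c in counts.items() if c >= 1}

    def test_spiked_fold_change_realized_in_expectation(self, reference):
        """A +2 log2FC spike yields a ~4x mean count ratio over seeds."""
        truth = synthdata.make_truth(reference, seed=13)
        up = next(
            m for m, fc in truth.log2fc[("A", "CK")].items()
            if fc == 2.0 and truth.abundance.at[m, "CK"] > 20
        )
        depth = 100_000
        ck_counts, a_counts = [], []
        for s in range(25):
            rng = np.random.default_rng(1000 + s)
            ck_counts.append(synthdata.simulate_counts(truth, "CK", depth, rng)[up])
            a_counts.append(synthdata.simulate_counts(truth, "A", depth, rng)[up])
        ratio = np.mean(a_counts) / np.mean(ck_counts)
        assert ratio == pytest.approx(4.0, rel=0.25)


class TestSimulateRace:
    def _duplex(self, reference):
        p = reference.planted_sites[0]
        mir = next(m for m in reference.mature_mirnas if m.id == p.mirna_id)
        tx = next(t for t in reference.transcripts if t.id == p.transcript_id)
        return score_duplex(
            mir.seq, tx.seq[p.start - 1 : p.end], mirna_id=mir.id,
            transcript_id=tx.id, start=p.start,
        )

    def test_degenerate_fractions(self, reference):
        duplex = self._duplex(reference)
        canon = duplex.canonical_cleavage_position()
        all_canon = synthdata.simulate_race_clones(duplex, 15, 1.0, seed=1)
        assert all_canon == [canon] * 15
        none_canon = synthdata.simulate_race_clones(duplex, 50, 0.0, seed=1)
        assert canon not in none_canon

    def test_positions_within_duplex_span(self, reference):
        duplex = self._duplex(reference)
        clones = synthdata.simulate_race_clones(duplex, 200, 0.5, seed=4)
        assert all(duplex.start <= p <= duplex.end for p in clones)

    def test_invalid_fraction_rejected(self, reference):
        with pytest.raises(ParameterError):
            synthdata.simulate_race_clones(self._duplex(reference), 10, 1.5, seed=1)


class TestSimulateQpcr:
    def test_noise_free_closed_form(self, reference):
        truth = synthdata.make_truth(reference, seed=17)
        from srnapipe.qpcr import ddct, ddct_table

        records = synthdata.simulate_qpcr(truth, ("A", "CK"), noise_sd=0.0, seed=1)
        table = ddct_table(records)
        spiked_up = [m for m in table.index if truth.log2fc[("A", "CK")][m] == 2.0]
        for m in spiked_up:
            assert table.at[m, "relative_expression"] == pytest.approx(4.0)

    def test_zero_fold_change_gives_unity(self, reference):
        truth = synthdata.make_truth(reference, seed=17)
        null_mirna = next(
            m for m, fc in truth.log2fc[("A", "CK")].items() if fc == 0.0
        )
        records = synthdata.simulate_qpcr(
            truth, ("A", "CK"), noise_sd=0.0, seed=1, mirnas=[null_mirna]
        )
        from srnapipe.qpcr import ddct

        assert ddct(records) == pytest.approx(1.0)

    def test_ct_noise_magnitude(self, reference):
        truth = synthdata.make_truth(reference, seed=17)
        records = synthdata.simulate_qpcr(
            truth, ("A", "CK"), noise_sd=0.2, seed=2,
            mirnas=sorted(truth.spiked[("A", "CK")]), n_bio=10, n_tech=10,
        )
        one = [r.ct_target for r in records if r.condition == "control"]
        assert np.std(one, ddof=1) == pytest.approx(0.2, rel=0.2)

    def test_negative_noise_rejected(self, reference):
        truth = synthdata.make_truth(reference, seed=17)
        with pytest.raises(ParameterError):
            synthdata.simulate_qpcr(truth, noise_sd=-0.1)
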