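"""Terminal-disorder detection and the five removal criteria."""

import itertools

import numpy as np
import pytest

from enzymespace.geometry import ResidueDescriptors
from enzymespace.structure import Atom, Chain, Residue, StructureModel
from enzymespace.synth import Segment, make_structure
from enzymespace.trimming import (
    Region,
    TrimCriteria,
    detect_unmodeled_regions,
    evaluate_region,
    lower_median,
    trim_structure,
)

from oracles import trim_criteria_oracle


def _score_model(scores):
    chain = Chain(id="A")
    for i, s in enumerate(scores):
        chain.residues.append(
            Residue(name="ALA", number=i + 1, chain_id="A",
                    atoms=[Atom("CA", "C", np.array([3.8 * i, 0.0, 0.0]))], score=float(s))
        )
    return StructureModel(chains=[chain])


class TestDetection:
    def test_high_score_prefix_is_an_N_terminal_region(self):
        model = _score_model([0.8] * 12 + [0.2] * 50)
        (region,) = detect_unmodeled_regions(model, disorder_threshold=0.5)
        assert (region.start, region.end, region.terminal) == (0, 11, "N")

    def test_confident_model_has_no_regions(self):
        model = _score_model([0.1] * 30)
        assert detect_unmodeled_regions(model, 0.5) == []

    def test_explicit_mask_gives_internal_region(self):
        model = _score_model([0.1] * 100)
        mask = {"A": [20 <= i <= 40 for i in range(100)]}
        (region,) = detect_unmodeled_regions(model, mask=mask)
        assert (region.start, region.end, region.terminal) == (20, 40, "internal")

    def test_c_terminal_run_tagged_C(self):
        model = _score_model([0.1] * 20 + [0.9] * 11)
        (region,) = detect_unmodeled_regions(model, 0.6)
        assert region.terminal == "C"

    def test_threshold_range_enforced(self):
        model = _score_model([0.1] * 5)
        with pytest.raises(ValueError):
            detect_unmodeled_regions(model, disorder_threshold=1.5)


def _fabricated(model_len, region, rel_sasa, contacts, ss_labels):
    """Hand-crafted descriptor table over a linear backbone."""
    model = _score_model([0.1] * model_len)
    desc = {
        f"A:{i + 1}": ResidueDescriptors(
            sasa=100.0 * rel_sasa[i], relative_sasa=rel_sasa[i],
            contact_density=contacts[i], ss_label=ss_labels[i],
        )
        for i in range(model_len)
    }
    return model, desc


class TestCriteriaBoundaries:
    """Exhaustive boundary grid checked against a hand-coded oracle."""

    @pytest.mark.parametrize("length", [9, 10, 15])
    @pytest.mark.parametrize("ss_len", [0, 5, 6])
    @pytest.mark.parametrize("sasa_level", [0.39, 0.41])
    @pytest.mark.parametrize("contact_level", [3, 4])
    @pytest.mark.parametrize("terminal", ["N", "internal"])
    def test_verdict_matches_oracle(self, length, ss_len, sasa_level, contact_level, terminal):
        model_len = 40
        start = 0 if terminal == "N" else 12
        end = start + length - 1
        labels = ["C"] * model_len
        for k in range(ss_len):  # SS element inside the region
            labels[start + k] = "H"
        rel = [0.8] * model_len
        con = [1] * model_len
        for i in range(start, end + 1):
            rel[i] = sasa_level
            con[i] = contact_level
        model, desc = _fabricated(model_len, None, rel, con, labels)
        region = Region("A", start, end, terminal)
        report = evaluate_region(region, model, desc)
        expected = trim_criteria_oracle(
            region_len=length,
            terminal=terminal,
            ss_element_lengths=[ss_len] if ss_len else [],
            rel_sasas=rel[start : end + 1],
            contacts=con[start : end + 1],
        )
        assert report.removable == expected

    def test_nine_residue_tail_fails_length_criterion(self):
        model, desc = _fabricated(30, None, [0.8] * 30, [1] * 30, ["C"] * 30)
        report = evaluate_region(Region("A", 0, 8, "N"), model, desc)
        assert not report.length_ok and not report.removable

    def test_internal_loop_fails_terminal_criterion(self):
        model, desc = _fabricated(40, None, [0.8] * 40, [1] * 40, ["C"] * 40)
        report = evaluate_region(Region("A", 10, 24, "internal"), model, desc)
        assert not report.terminal_ok and not report.removable
        assert all(report.criteria()[:4])

    def test_intersecting_long_ss_element_fails(self):
        # 7-residue helix crossing the region boundary
        labels = ["C"] * 30
        for k in range(8, 15):
            labels[k] = "H"
        model, desc = _fabricated(30, None, [0.8] * 30, [1] * 30, labels)
        report = evaluate_region(Region("A", 0, 11, "N"), model, desc)
        assert not report.ss_ok
        assert report.longest_ss_element == 7

    def test_lower_median_convention(self):
        assert lower_median([1, 2, 3, 4]) == 2
        assert lower_median([0.3, 0.5]) == 0.3
        assert lower_median([7]) == 7


class TestTrimStructure:
    def test_removable_tail_deleted_exactly(self, helix_tail_model):
        trimmed, reports = trim_structure(helix_tail_model)
        assert helix_tail_model.n_residues - trimmed.n_residues == 12
        removed = [r for r in reports if r.removable]
        assert len(removed) == 1 and removed[0].region.terminal == "N"
        # numbering of retained residues preserved
        assert [r.number for r in trimmed.residues()] == list(range(13, 43))

    def test_confident_model_untouched(self):
        model = make_structure([Segment("helix", 25, 0.1)], seed=3)
        trimmed, reports = trim_structure(model)
        assert trimmed.n_residues == model.n_residues
        assert not any(r.removable for r in reports)

    def test_tail_containing_long_helix_retained(self):
        model = make_structure(
            [Segment("helix", 7, 0.8), Segment("coil", 5, 0.8), Segment("helix", 30, 0.1)],
            seed=4,
        )
        trimmed, reports = trim_structure(model)
        assert trimmed.n_residues == model.n_residues
        bad = [r for r in reports if not r.ss_ok]
        assert bad  # the 7-residue helix vetoed the removal

    def test_idempotent_in_single_pass_mode(self, helix_tail_model):
        once, _ = trim_structure(helix_tail_model)
        twice, _ = trim_structure(once)
        assert [r.number for r in twice.residues()] == [r.number for r in once.residues()]

    def test_whole_chain_removal_refused(self):
        model = _score_model([0.9] * 20)
        # spread the residues out so the tail is exposed and contact-free
        trimmed, reports = trim_structure(model)
        assert trimmed.n_residues == 20
        assert any(r.refused for r in reports)

    def test_report_matches_deleted_residue_count(self, helix_tail_model):
        trimmed, reports = trim_structure(helix_tail_model)
        expected = sum(len(r.region) for r in reports if r.removable and not r.refused)
        assert helix_tail_model.n_residues - trimmed.n_residues == expected

    def test_raising_sasa_threshold_only_shrinks_removal(self, helix_tail_model):
        loose, _ = trim_structure(helix_tail_model, TrimCriteria(min_median_rel_sasa=0.40))
        strict, _ = trim_structure(helix_tail_model, TrimCriteria(min_median_rel_sasa=0.95))
        assert strict.n_residues >= loose.n_residues

    def test_input_model_not_modified(self, helix_tail_model):
        before = helix_tail_model.n_residues
        trim_structure(helix_tail_model)
        assert helix_tail_model.n_residues == before
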