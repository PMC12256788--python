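import pytest

from mitotriage import io as mio
from mitotriage.variant_filter import (
    HaplogroupMarkerTable,
    MtVariantRecord,
    SampleQC,
    VariantAnnotation,
    apply_sample_qc,
    assign_haplogroup,
    filter_cohort,
    is_haplogroup_marker,
    passes_prioritization,
)

from importlib import resources


def demo_path(name):
    return resources.files("mitotriage").joinpath(f"data/demo/{name}")


@pytest.fixture(scope="module")
def demo():
    with resources.as_file(demo_path("qc.tsv")) as p:
        qc = mio.read_qc_tsv(p)
    with resources.as_file(demo_path("variants.tsv")) as p:
        calls = mio.read_variants_tsv(p)
    with resources.as_file(demo_path("annotations.tsv")) as p:
        ann = mio.read_annotations_tsv(p)
    with resources.as_file(demo_path("markers.tsv")) as p:
        markers = mio.read_markers_tsv(p)
    return qc, calls, ann, markers


class TestSampleQC:
    @pytest.mark.parametrize("fraction,depth,passed,reasons", [
        (0.49, 10.0, False, ("assembly",)),
        (0.50, 5.0, True, ()),
        (1.00, 4.9, False, ("depth",)),
        (0.10, 1.0, False, ("assembly", "depth")),
    ])
    def test_inclusive_thresholds(self, fraction, depth, passed, reasons):
        r = apply_sample_qc(SampleQC("s", fraction, depth))
        assert r.passed is passed
        assert r.reasons == reasons


class TestHaplogroupAssignment:
    MARKERS = HaplogroupMarkerTable(markers={
        "H": {(1, "A", "C"), (2, "A", "C"), (3, "A", "C")},
        "J": {(4, "A", "C"), (5, "A", "C"), (6, "A", "C"), (7, "A", "C")},
    })

    def _var(self, pos, het=1.0):
        return MtVariantRecord("s", pos, "A", "C", het)

    def test_full_marker_set_wins(self):
        hg, frac = assign_haplogroup(
            [self._var(1), self._var(2), self._var(3)], self.MARKERS)
        assert (hg, frac) == ("H", 1.0)

    def test_best_fraction_wins(self):
        # 1/3 of H (0.33) beats 1/4 of J (0.25)
        hg, frac = assign_haplogroup([self._var(1), self._var(4)],
                                     self.MARKERS)
        assert hg == "H"
        assert frac == pytest.approx(1 / 3)

    def test_no_overlap_ties_break_lexicographically(self):
        hg, frac = assign_haplogroup([self._var(100)], self.MARKERS)
        assert (hg, frac) == ("H", 0.0)

    def test_low_heteroplasmy_variants_do_not_count(self):
        hg, frac = assign_haplogroup(
            [self._var(4, het=0.3), self._var(1)], self.MARKERS)
        assert hg == "H"

    def test_marker_membership(self):
        v = self._var(1)
        assert is_haplogroup_marker(v, "H", self.MARKERS)
        assert not is_haplogroup_marker(v, "J", self.MARKERS)
        with pytest.raises(KeyError):
            is_haplogroup_marker(v, "Z", self.MARKERS)


class TestPrioritization:
    def _var(self, het):
        return MtVariantRecord("s", 3243, "A", "G", het)

    def _ann(self, status="absent", af=None, mitophen=False):
        return VariantAnnotation(3243, "A", "G", mitomap_status=status,
                                 mitomap_af=af, in_mitophen=mitophen)

    def test_confirmed_with_sufficient_heteroplasmy(self):
        r = passes_prioritization(self._var(0.33), self._ann("confirmed"))
        assert r.passed and r.criterion == "confirmed"

    def test_heteroplasmy_floor_is_mandatory(self):
        assert not passes_prioritization(self._var(0.005),
                                         self._ann("confirmed")).passed

    def test_heteroplasmy_floor_inclusive(self):
        assert passes_prioritization(self._var(0.01),
                                     self._ann("confirmed")).passed

    def test_reported_requires_af_strictly_below_ceiling(self):
        assert not passes_prioritization(
            self._var(0.5), self._ann("reported", af=0.003)).passed
        assert not passes_prioritization(
            self._var(0.5), self._ann("reported", af=0.002)).passed
        r = passes_prioritization(self._var(0.5),
                                  self._ann("reported", af=0.0019))
        assert r.passed and r.criterion == "reported_rare"

    def test_phenotype_database_membership_suffices(self):
        r = passes_prioritization(self._var(0.5),
                                  self._ann("absent", mitophen=True))
        assert r.passed and r.criterion == "mitophen"

    def test_criterion_priority_order(self):
        r = passes_prioritization(
            self._var(0.5), self._ann("confirmed", af=0.0001, mitophen=True))
        assert r.criterion == "confirmed"

    def test_reported_without_af_fails_frequency_clause(self):
        assert not passes_prioritization(self._var(0.5),
                                         self._ann("reported")).passed

    def test_unannotated_variant_fails(self):
        assert not passes_prioritization(self._var(0.5), None).passed


class TestFilterCohort:
    EXPECTED_SURVIVORS = {
        ("S1", (3243, "A", "G"), "confirmed"),
        ("S2", (8344, "A", "G"), "confirmed"),
        ("S2", (1555, "A", "G"), "mitophen"),
        ("S4", (8993, "T", "G"), "reported_rare"),
    }

    def test_fixture_survivors_exact(self, demo):
        qc, calls, ann, markers = demo
        fr = filter_cohort(qc, calls, ann, markers)
        got = {(c.sample_id, c.key, c.criterion) for c in fr.candidates}
        assert got == self.EXPECTED_SURVIVORS

    def test_fixture_funnel_counts(self, demo):
        qc, calls, ann, markers = demo
        fr = filter_cohort(qc, calls, ann, markers)
        assert fr.funnel == {
            "samples_total": 5, "samples_pass_qc": 3, "variants_total": 20,
            "dropped_qc": 4, "dropped_marker": 5,
            "dropped_prioritization": 7, "candidates": 4,
        }
        assert fr.sample_haplogroups == {"S1": "H", "S2": "J", "S4": "H"}

    def test_every_candidate_satisfies_all_gates_post_hoc(self, demo):
        qc, calls, ann, markers = demo
        fr = filter_cohort(qc, calls, ann, markers)
        qc_map = {q.sample_id: q for q in qc}
        for c in fr.candidates:
            assert apply_sample_qc(qc_map[c.sample_id]).passed
            v = MtVariantRecord(c.sample_id, c.position, c.ref, c.alt,
                                c.heteroplasmy, c.depth)
            assert not is_haplogroup_marker(v, c.haplogroup, markers)
            assert passes_prioritization(v, ann.get(c.key)).passed

    def test_all_samples_failing_qc_yields_empty(self, demo):
        _, calls, ann, markers = demo
        bad_qc = [SampleQC(s, 0.1, 1.0)
                  for s in sorted({v.sample_id for v in calls})]
        fr = filter_cohort(bad_qc, calls, ann, markers)
        assert fr.candidates == []
        assert fr.funnel["dropped_qc"] == len(calls)

    def test_sample_missing_from_qc_table_is_hard_error(self, demo):
        qc, calls, ann, markers = demo
        with pytest.raises(ValueError, match="missing from QC"):
            filter_cohort(qc[:-1][:2], calls, ann, markers)

    def test_precomputed_haplogroups_take_precedence(self, demo):
        qc, calls, ann, markers = demo
        fr = filter_cohort(qc, calls, ann, markers,
                           haplogroups={"S1": "J", "S2": "J", "S4": "H"})
        # S1's H markers (7028, 2706) are no longer excluded, but they are
        # unannotated so they fail prioritization instead; survivor set holds.
        got = {(c.sample_id, c.key, c.criterion) for c in fr.candidates}
        assert got == self.EXPECTED_SURVIVORS
        assert fr.funnel["dropped_marker"] == 3

    def test_stability_across_runs(self, demo):
        qc, calls, ann, markers = demo
        a = filter_cohort(qc, calls, ann, markers)
        b = filter_cohort(qc, calls, ann, markers)
        assert [c.__dict__ for c in a.candidates] == \
               [c.__dict__ for c in b.candidates]


class TestRecordValidation:
    def test_position_bounds(self):
        with pytest.raises(ValueError):
            MtVariantRecord("s", 0, "A", "G", 0.5)
        with pytest.raises(ValueError):
            MtVariantRecord("s", 16570, "A", "G", 0.5)

    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError):
            MtVariantRecord("s", 100, "A", "A", 0.5)

    def test_heteroplasmy_range(self):
        with pytest.raises(ValueError):
            MtVariantRecord("s", 100, "A", "G", 1.5)
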