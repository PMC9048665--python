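import json

import pytest

from rvescore.annotation import load_bundle
from rvescore.errors import ValidationError
from rvescore.rubric import load_default_rubric, max_scores
from rvescore.scoring import ReferenceDistribution, compute_scores
from rvescore.variant import VariantSpec
from rvescore.workflow import (
    Session,
    finalize,
    load_session,
    replay_audit,
    save_session,
    step1_auto,
    step2_manual,
    step3_override,
)


@pytest.fixture
def rubric():
    return load_default_rubric()


@pytest.fixture
def planted_variant():
    return VariantSpec(assembly="GRCh38", chrom="chr1", pos=150_000, ref="G", alt="A",
                       gene="GENE1")


@pytest.fixture
def reference(fixture_bundle_dir):
    return ReferenceDistribution.from_tsv(
        fixture_bundle_dir / "reference_synthetic.tsv", expected_size=None
    )


def _session_after_step1(rubric, planted_variant, bundle_dir):
    session = Session(variant=planted_variant, rubric=rubric)
    step1_auto(session, load_bundle(bundle_dir / "manifest.yaml"))
    return session


class TestStep1:
    def test_all_pass_bundle_sets_every_auto_criterion_to_one(
        self, rubric, planted_variant, fixture_bundle_dir
    ):
        session = _session_after_step1(rubric, planted_variant, fixture_bundle_dir)
        key = json.loads((fixture_bundle_dir / "key.json").read_text())
        for cid, expected in key["expected_auto_evidence"].items():
            assert session.evidence[cid].value == expected == 1
            assert session.evidence[cid].provenance == "auto"
            assert session.evidence[cid].raw is not None

    def test_no_coverage_bundle_sets_every_auto_criterion_to_zero(
        self, rubric, planted_variant, nocov_bundle_dir
    ):
        session = _session_after_step1(rubric, planted_variant, nocov_bundle_dir)
        for c in rubric.auto_criteria():
            assert session.evidence[c.id].value == 0
            assert session.evidence[c.id].raw.status == "missing"

    def test_rerunning_step1_is_idempotent_and_audited(
        self, rubric, planted_variant, fixture_bundle_dir
    ):
        session = _session_after_step1(rubric, planted_variant, fixture_bundle_dir)
        before = dict(session.evidence)
        n_audit = len(session.audit)
        step1_auto(session, load_bundle(fixture_bundle_dir / "manifest.yaml"))
        assert dict(session.evidence) == before
        assert len(session.audit) == 2 * n_audit  # the replay is recorded


class TestStep2:
    def test_yes_no_and_unanswered(self, rubric, planted_variant, fixture_bundle_dir):
        session = _session_after_step1(rubric, planted_variant, fixture_bundle_dir)
        step2_manual(session, {"C3.1": "yes", "C2.1": "no"})
        assert session.evidence["C3.1"].value == 1
        assert session.evidence["C3.1"].provenance == "user_answer"
        assert session.evidence["C2.1"].value == 0
        assert session.evidence["C2.1"].provenance == "user_answer"
        # every other manual criterion defaults to 0 / unknown
        for c in rubric.manual_criteria():
            if c.id in ("C3.1", "C2.1"):
                continue
            assert session.evidence[c.id].value == 0
            assert session.evidence[c.id].provenance == "default_unknown"

    def test_answer_for_auto_criterion_rejected(self, rubric, planted_variant,
                                                fixture_bundle_dir):
        session = _session_after_step1(rubric, planted_variant, fixture_bundle_dir)
        with pytest.raises(ValidationError, match="automatic"):
            step2_manual(session, {"C1.1": "yes"})

    def test_step_ordering_enforced(self, rubric, planted_variant):
        session = Session(variant=planted_variant, rubric=rubric)
        with pytest.raises(ValidationError, match="step 1"):
            step2_manual(session, {})
        with pytest.raises(ValidationError, match="steps 1 and 2"):
            step3_override(session, {})


class TestStep3:
    def _through_step2(self, rubric, planted_variant, bundle_dir):
        session = _session_after_step1(rubric, planted_variant, bundle_dir)
        return step2_manual(session, {})

    def test_override_retains_previous_value_and_comment(
        self, rubric, planted_variant, nocov_bundle_dir
    ):
        session = self._through_step2(rubric, planted_variant, nocov_bundle_dir)
        assert session.evidence["F1.1"].value == 0
        step3_override(session, {"F1.1": (1, "conservation reported in Fig 2 of PMID:000")})
        ev = session.evidence["F1.1"]
        assert ev.value == 1 and ev.provenance == "user_override"
        assert ev.previous_value == 0
        last = session.audit[-1]
        assert (last.old_value, last.new_value) == (0, 1)
        assert "PMID" in last.comment

    def test_forced_value_outside_binary_rejected(self, rubric, planted_variant,
                                                  nocov_bundle_dir):
        session = self._through_step2(rubric, planted_variant, nocov_bundle_dir)
        with pytest.raises(ValidationError, match="0 or 1"):
            step3_override(session, {"F1.1": (2, "")})

    def test_empty_overrides_leave_session_unchanged(self, rubric, planted_variant,
                                                     nocov_bundle_dir):
        session = self._through_step2(rubric, planted_variant, nocov_bundle_dir)
        before = dict(session.evidence)
        step3_override(session, {})
        assert dict(session.evidence) == before


class TestAuditReplay:
    def test_replay_reproduces_final_evidence(self, rubric, planted_variant,
                                              fixture_bundle_dir):
        session = _session_after_step1(rubric, planted_variant, fixture_bundle_dir)
        step2_manual(session, {"C3.1": "yes", "F2.1": "no"})
        step3_override(session, {"C1.1": (0, "local cohort carries the allele"),
                                 "F4.1": (1, "zebrafish model, PMID:111")})
        replayed = replay_audit(planted_variant, rubric, session.audit)
        assert dict(replayed) == dict(session.evidence)

    def test_snapshot_round_trip(self, rubric, planted_variant, fixture_bundle_dir,
                                 tmp_path):
        session = _session_after_step1(rubric, planted_variant, fixture_bundle_dir)
        step2_manual(session, {"C3.1": "yes"})
        path = tmp_path / "session.json"
        save_session(session, path)
        restored = load_session(path, rubric)
        assert dict(restored.evidence) == dict(session.evidence)
        assert restored.audit == session.audit
        assert restored.completed_steps == session.completed_steps

    def test_snapshot_schema_version_checked(self, rubric, planted_variant,
                                             fixture_bundle_dir, tmp_path):
        session = _session_after_step1(rubric, planted_variant, fixture_bundle_dir)
        path = tmp_path / "session.json"
        save_session(session, path)
        payload = json.loads(path.read_text())
        payload["schema_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(ValidationError, match="schema version"):
            load_session(path, rubric)


class TestFinalize:
    def test_zero_evidence_session_scores_zero(self, rubric, planted_variant,
                                               nocov_bundle_dir, reference):
        session = _session_after_step1(rubric, planted_variant, nocov_bundle_dir)
        result = finalize(session, reference)
        assert (result.c_score, result.f_score, result.rve_score) == (0, 0, 0)
        assert result.percentile is not None

    def test_matches_direct_scoring_oracle(self, rubric, planted_variant,
                                           fixture_bundle_dir, reference):
        session = _session_after_step1(rubric, planted_variant, fixture_bundle_dir)
        step2_manual(session, {"C2.1": "yes", "F3.1": "yes"})
        result = finalize(session, reference)
        direct = compute_scores(session.evidence, rubric)
        assert (result.c_score, result.f_score, result.rve_score) == (
            direct.c_score, direct.f_score, direct.rve_score
        )

    def test_finalize_is_pure_and_deterministic(self, rubric, planted_variant,
                                                fixture_bundle_dir, reference):
        session = _session_after_step1(rubric, planted_variant, fixture_bundle_dir)
        evidence_before = dict(session.evidence)
        r1 = finalize(session, reference)
        r2 = finalize(session, reference)
        assert r1 == r2
        assert dict(session.evidence) == evidence_before

    def test_all_yes_saturates_at_max(self, rubric, planted_variant,
                                      fixture_bundle_dir, reference):
        session = _session_after_step1(rubric, planted_variant, fixture_bundle_dir)
        step2_manual(session, {c.id: "yes" for c in rubric.manual_criteria()})
        result = finalize(session, reference)
        max_c, max_f = max_scores(rubric)
        assert (result.c_score, result.f_score) == (max_c, max_f)
        assert result.percentile == 100.0
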