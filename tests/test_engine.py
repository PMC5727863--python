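"""Token game: care-flow patterns, triggers, clocks, enumeration, replay."""

import numpy as np
import pytest

from dynacheck.context import ContextSchema, FieldSpec, PatientContext
from dynacheck.engine import (
    advance_clock,
    complete_guard,
    complete_task,
    enabled_tasks,
    enter_guard,
    enter_task,
    legal_completion_orders,
    replay_log,
    simulate_case,
    start_case,
)
from dynacheck.errors import (
    InvalidModelError,
    NotEnabledError,
    RoleMismatchError,
    TooLargeError,
)
from dynacheck.expressions import parse_expression
from dynacheck.model import (
    AdHocBlock,
    ChecklistForm,
    CheckableItem,
    ClinicalTask,
    Edge,
    EventNode,
    GatewayNode,
    Pathway,
    PotentialOwner,
    Role,
    SafetyGuardBinding,
    TargetClinicalProblem,
    Trigger,
    resolve_model,
)

from _helpers import oracle_completion_orders, random_structured_pathway

NURSE = Role("nurse", "nurse")
SURGEON = Role("surgeon", "surgeon")


def form(fid="f"):
    return ChecklistForm(
        id=fid,
        problems=(TargetClinicalProblem(
            id=f"{fid}_p", description="",
            static_items=(CheckableItem(id=f"{fid}_i", description="check"),),
        ),),
    )


def build(nodes, edges, roles=(NURSE,), forms=(), schema=None):
    pw = Pathway(
        id="p",
        nodes=(EventNode("start", "start"), EventNode("end", "end"), *nodes),
        edges=tuple(Edge(f"e{i}", s, t) for i, (s, t) in enumerate(edges)),
        start_node_id="start", end_node_id="end", roles=tuple(roles),
    )
    return resolve_model(pw, forms, [], schema or ContextSchema())


def task(tid, roles={"nurse"}, guards=()):
    return ClinicalTask(id=tid, name=tid, role_ids=frozenset(roles), guards=tuple(guards))


def linear_model(guards_on_a=()):
    return build(
        [task("A", guards=guards_on_a), task("B")],
        [("start", "A"), ("A", "B"), ("B", "end")],
        forms=[form()] if guards_on_a else (),
    )


def names(state):
    return {t for t, _ in enabled_tasks(state)}


class TestLifecycle:
    def test_start_enables_first_task_only(self):
        state = start_case(linear_model(), "p1", "c1")
        assert names(state) == {"A"}
        assert any(e.kind == "CASE_STARTED" for e in state.log)

    def test_invalid_model_rejected(self):
        bad = build([task("A", roles={"ghost"}), task("B")],
                    [("start", "A"), ("A", "B"), ("B", "end")])
        with pytest.raises(InvalidModelError):
            start_case(bad, "p1", "c1")

    def test_completion_advances_and_closes_case(self):
        state = start_case(linear_model(), "p1", "c1")
        state, _ = complete_task(state, "A")
        assert names(state) == {"B"}
        state, _ = complete_task(state, "B")
        assert state.complete and names(state) == set()

    def test_completing_a_dormant_task_fails(self):
        state = start_case(linear_model(), "p1", "c1")
        with pytest.raises(NotEnabledError):
            complete_task(state, "B")

    def test_role_mismatch(self):
        model = build(
            [task("A", roles={"surgeon"}), task("B")],
            [("start", "A"), ("A", "B"), ("B", "end")],
            roles=(NURSE, SURGEON),
        )
        state = start_case(model, "p1", "c1")
        nurse = PotentialOwner("n1", "nina", frozenset({"nurse"}))
        with pytest.raises(RoleMismatchError):
            complete_task(state, "A", nurse)
        surgeon = PotentialOwner("s1", "sam", frozenset({"surgeon"}))
        state, _ = complete_task(state, "A", surgeon)
        assert names(state) == {"B"}

    def test_operations_do_not_mutate_their_input(self):
        state = start_case(linear_model(), "p1", "c1")
        complete_task(state, "A")
        assert names(state) == {"A"}  # original untouched


class TestParallel:
    def model(self):
        return build(
            [task("A"), task("B"), task("C"), task("D"),
             GatewayNode("s", "parallel_split"), GatewayNode("j", "parallel_join")],
            [("start", "A"), ("A", "s"), ("s", "B"), ("s", "C"),
             ("B", "j"), ("C", "j"), ("j", "D"), ("D", "end")],
        )

    def test_both_branches_enabled_after_split(self):
        state = start_case(self.model(), "p1", "c1")
        state, _ = complete_task(state, "A")
        assert names(state) == {"B", "C"}

    def test_join_waits_for_both_branches(self):
        state = start_case(self.model(), "p1", "c1")
        state, _ = complete_task(state, "A")
        state, _ = complete_task(state, "B")
        assert names(state) == {"C"}
        state, _ = complete_task(state, "C")
        assert names(state) == {"D"}

    def test_join_token_count_never_exceeds_fan_in(self):
        state = start_case(self.model(), "p1", "c1")
        for t in ("A", "B", "C", "D"):
            state, _ = complete_task(state, t)
            join_tokens = state.tokens["e4"] + state.tokens["e5"]
            assert join_tokens <= 2
        assert state.complete


class TestExclusive:
    def model(self):
        schema = ContextSchema.from_specs([FieldSpec("lvef", "number")])
        split = GatewayNode(
            "x", "exclusive_split",
            branch_conditions=(("e1", parse_expression("lvef < 50")),),
            default_edge_id="e2",
        )
        nodes = [task("LOWEF"), task("NORMAL"), split, GatewayNode("m", "exclusive_merge")]
        edges = [("start", "x"), ("x", "LOWEF"), ("x", "NORMAL"),
                 ("LOWEF", "m"), ("NORMAL", "m"), ("m", "end")]
        return build(nodes, edges, schema=schema)

    def test_true_condition_takes_the_conditional_branch(self):
        ctx = PatientContext("p", {"lvef": 36})
        state = start_case(self.model(), "p", "c", ctx)
        assert names(state) == {"LOWEF"}

    def test_false_condition_takes_the_default(self):
        ctx = PatientContext("p", {"lvef": 70})
        state = start_case(self.model(), "p", "c", ctx)
        assert names(state) == {"NORMAL"}

    def test_unknown_condition_falls_through_to_default(self):
        state = start_case(self.model(), "p", "c", PatientContext("p", {}))
        assert names(state) == {"NORMAL"}

    def test_exactly_one_branch_activated(self):
        ctx = PatientContext("p", {"lvef": 36})
        state = start_case(self.model(), "p", "c", ctx)
        assert sum(state.tokens.values()) == 1


class TestInclusive:
    def model(self):
        schema = ContextSchema.from_specs(
            [FieldSpec("a", "boolean"), FieldSpec("b", "boolean")]
        )
        split = GatewayNode(
            "x", "inclusive_split",
            branch_conditions=(
                ("e1", parse_expression("a == true")),
                ("e2", parse_expression("b == true")),
            ),
            default_edge_id="e3",
        )
        nodes = [task("TA"), task("TB"), task("TD"), task("AFTER"),
                 split, GatewayNode("j", "inclusive_join")]
        edges = [("start", "x"), ("x", "TA"), ("x", "TB"), ("x", "TD"),
                 ("TA", "j"), ("TB", "j"), ("TD", "j"), ("j", "AFTER"),
                 ("AFTER", "end")]
        return build(nodes, edges, schema=schema)

    def test_every_true_branch_activates(self):
        ctx = PatientContext("p", {"a": True, "b": True})
        state = start_case(self.model(), "p", "c", ctx)
        assert names(state) == {"TA", "TB"}

    def test_join_waits_for_exactly_the_activated_branches(self):
        ctx = PatientContext("p", {"a": True, "b": True})
        state = start_case(self.model(), "p", "c", ctx)
        state, _ = complete_task(state, "TA")
        assert names(state) == {"TB"}
        state, _ = complete_task(state, "TB")
        assert names(state) == {"AFTER"}

    def test_no_true_branch_takes_default_only(self):
        ctx = PatientContext("p", {"a": False, "b": False})
        state = start_case(self.model(), "p", "c", ctx)
        assert names(state) == {"TD"}
        state, _ = complete_task(state, "TD")
        assert names(state) == {"AFTER"}


class TestAdHoc:
    def model(self, mandatory=("B", "C")):
        block = AdHocBlock("ah", task_ids=frozenset({"B", "C"}),
                           mandatory_task_ids=frozenset(mandatory))
        return build(
            [task("A"), task("B"), task("C"), task("D"), block],
            [("start", "A"), ("A", "ah"), ("ah", "D"), ("D", "end")],
        )

    def test_all_members_enabled_on_entry(self):
        state = start_case(self.model(), "p", "c")
        state, _ = complete_task(state, "A")
        assert names(state) == {"B", "C"}

    def test_block_completes_after_mandatory_members(self):
        state = start_case(self.model(), "p", "c")
        state, _ = complete_task(state, "A")
        state, _ = complete_task(state, "C")
        assert names(state) == {"B"}
        state, _ = complete_task(state, "B")
        assert names(state) == {"D"}

    def test_optional_member_skipped_when_mandatory_done(self):
        state = start_case(self.model(mandatory=("B",)), "p", "c")
        state, _ = complete_task(state, "A")
        state, _ = complete_task(state, "B")
        assert state.state_of("C") == "skipped"
        assert names(state) == {"D"}


class TestGuards:
    def entry_binding(self, blocking=False, sub=()):
        return SafetyGuardBinding(
            trigger=Trigger("on_entry"), form_id="f", blocking=blocking,
            guards=tuple(sub),
        )

    def test_entry_trigger_yields_one_open_activation(self):
        model = linear_model(guards_on_a=[self.entry_binding()])
        state = start_case(model, "p", "c")
        state, fired = enter_task(state, "A")
        assert len(fired) == 1 and fired[0].state == "open"
        assert fired[0].guard.form_id == "f"

    def test_task_without_guards_yields_none(self):
        state = start_case(linear_model(), "p", "c")
        _, fired = enter_task(state, "A")
        assert fired == []

    def test_guard_on_guard_yields_second_level_activation(self):
        nested = SafetyGuardBinding(trigger=Trigger("on_entry"), form_id="f")
        model = linear_model(guards_on_a=[self.entry_binding(sub=[nested])])
        state = start_case(model, "p", "c")
        state, level1 = enter_task(state, "A")
        state, level2 = enter_guard(state, level1[0].instance_id)
        assert len(level2) == 1 and level2[0].guard.form_id == "f"

    def test_exit_trigger_fires_on_completion(self):
        binding = SafetyGuardBinding(trigger=Trigger("on_exit"), form_id="f")
        model = linear_model(guards_on_a=[binding])
        state = start_case(model, "p", "c")
        state, fired = complete_task(state, "A")
        assert [g.guard.trigger.kind for g in fired] == ["on_exit"]

    def test_blocking_guard_gates_completion(self):
        model = linear_model(guards_on_a=[self.entry_binding(blocking=True)])
        state = start_case(model, "p", "c")
        state, fired = enter_task(state, "A")
        from dynacheck.engine import GuardPendingError
        with pytest.raises(GuardPendingError):
            complete_task(state, "A")
        state, _ = enter_guard(state, fired[0].instance_id)
        state, _ = complete_guard(state, fired[0].instance_id)
        state, _ = complete_task(state, "A")
        assert names(state) == {"B"}


class TestOverdue:
    def model(self):
        binding = SafetyGuardBinding(
            trigger=Trigger("overdue", overdue_after=60), form_id="f"
        )
        return linear_model(guards_on_a=[binding])

    def test_threshold_crossing_fires_exactly_once(self):
        state = start_case(self.model(), "p", "c")
        state, fired = advance_clock(state, 59)
        assert fired == []
        state, fired = advance_clock(state, 2)
        assert len(fired) == 1
        state, fired = advance_clock(state, 100)
        assert fired == []  # never re-fires

    def test_completed_task_never_goes_overdue(self):
        state = start_case(self.model(), "p", "c")
        state, _ = complete_task(state, "A")
        state, fired = advance_clock(state, 500)
        assert fired == []


class TestLegalOrders:
    def adhoc_model(self, members):
        block = AdHocBlock("ah", task_ids=frozenset(members),
                           mandatory_task_ids=frozenset(members))
        return build(
            [block] + [task(m) for m in members],
            [("start", "ah"), ("ah", "end")],
        )

    @pytest.mark.parametrize("members, expected", [(("B", "C"), 2), (("B", "C", "D"), 6)])
    def test_adhoc_orders_are_factorial(self, members, expected):
        assert len(legal_completion_orders(self.adhoc_model(members))) == expected

    def test_linear_pathway_has_one_order(self):
        assert legal_completion_orders(linear_model()) == {("A", "B")}

    def test_too_large_guard(self, cabg):
        with pytest.raises(TooLargeError):
            legal_completion_orders(cabg)

    def test_matches_independent_oracle_on_random_pathways(self):
        rng = np.random.default_rng(20240915)
        checked = 0
        while checked < 12:
            model = random_structured_pathway(rng)
            if len(model.pathway.tasks()) > 6:
                continue
            got = legal_completion_orders(model)
            want = oracle_completion_orders(model.pathway)
            assert got == want, model.pathway.id
            checked += 1


class TestConservationAndReplay:
    def test_token_conservation_on_fuzzed_parallel_runs(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            model = random_structured_pathway(rng)
            ctx = PatientContext("p", {"flag": bool(rng.integers(2))})
            state = simulate_case(model, ctx, seed=int(rng.integers(2**31)))
            assert state.complete
            assert sum(state.tokens.values()) == 0  # all tokens consumed at end

    def test_replay_reproduces_final_state(self):
        model = TestParallel().model()
        ctx = PatientContext("p", {})
        state = start_case(model, "p", "c1", ctx)
        for t in ("A", "C", "B", "D"):
            state, _ = enter_task(state, t)
            state, _ = complete_task(state, t)
        replayed = replay_log(model, ctx, state.log)
        assert replayed.task_states == state.task_states
        assert replayed.tokens == state.tokens
        assert replayed.complete == state.complete
        assert [e.kind for e in replayed.log] == [e.kind for e in state.log]
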