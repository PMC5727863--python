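"""The WHEN/THEN rule DSL.

One statement per rule::

    RULE <id> [FOR <problem_id>] WHEN <condition> THEN <action> [AND <action>]*

Actions::

    add_item [<item_id>] "text with {field} slots" [guidance] [priority high]
    highlight <item_id> red
    pre_check <item_id>
    set_priority <item_id> high|normal
    attach_material <item_id> patient_data <field>
    attach_material <item_id> literature "citation or URI"
    invoke_rule <rule_id>

``add_item`` without an explicit item id names the created item
``<rule_id>_item``. Keywords are case-insensitive; ids are case-sensitive.
Every malformed input raises a located :class:`ParseError` — the parser is
total over byte sequences.
"""

from __future__ import annotations

from .errors import DuplicateRuleIdError, ParseError
from .expressions import Expression, Token, _ExprParser, tokenize
from .model import DEFAULT_OPTIONS, CheckableItem, SupplementaryMaterial, valid_id
from .rules import Action, Rule

_ACTION_KEYWORDS = {
    "add_item",
    "highlight",
    "pre_check",
    "set_priority",
    "attach_material",
    "invoke_rule",
}


def _kw(tok: Token, word: str) -> bool:
    return tok.kind in ("ident", "and") and tok.text.upper() == word.upper()


class _DslParser:
    def __init__(self, text: str):
        try:
            self.tokens = list(tokenize(text))
        except ParseError:
            raise
        self.i = 0

    @property
    def cur(self) -> Token:
        return self.tokens[self.i]

    def advance(self) -> Token:
        t = self.cur
        self.i += 1
        return t

    def fail(self, msg: str, tok: Token | None = None):
        t = tok or self.cur
        raise ParseError(msg, t.line, t.column)

    def expect_ident(self, what: str) -> Token:
        if self.cur.kind != "ident":
            self.fail(f"expected {what}, found {self.cur.text!r}")
        return self.advance()

    def expect_string(self, what: str) -> str:
        if self.cur.kind != "string":
            self.fail(f"expected {what} (a quoted string), found {self.cur.text!r}")
        from .expressions import _unquote

        return _unquote(self.advance().text)

    def parse_file(self) -> list[Rule]:
        rules: list[Rule] = []
        seen: set[str] = set()
        while self.cur.kind != "eof":
            rule = self.parse_statement()
            if rule.id in seen:
                raise DuplicateRuleIdError(f"rule id {rule.id!r} defined twice")
            seen.add(rule.id)
            rules.append(rule)
        return rules

    def parse_statement(self) -> Rule:
        if not _kw(self.cur, "RULE"):
            self.fail(f"expected 'RULE', found {self.cur.text!r}")
        self.advance()
        rid_tok = self.expect_ident("a rule id")
        if not valid_id(rid_tok.text):
            self.fail(f"bad rule id {rid_tok.text!r}", rid_tok)
        problem_id = None
        if _kw(self.cur, "FOR"):
            self.advance()
            problem_id = self.expect_ident("a problem id").text
        if not _kw(self.cur, "WHEN"):
            self.fail(f"expected 'WHEN', found {self.cur.text!r}")
        self.advance()
        condition = self.parse_condition()
        actions = [self.parse_action(rid_tok.text)]
        while self.cur.kind == "and":
            self.advance()
            actions.append(self.parse_action(rid_tok.text))
        return Rule(
            id=rid_tok.text,
            condition=condition,
            actions=tuple(actions),
            problem_id=problem_id,
        )

    def parse_condition(self) -> Expression:
        """Collect tokens up to THEN (at paren depth 0), parse as expression."""
        start = self.i
        depth = 0
        while True:
            t = self.cur
            if t.kind == "eof":
                last = self.tokens[self.i - 1] if self.i > start else t
                raise ParseError(
                    "expected 'THEN' after the WHEN condition", last.line, last.column
                )
            if t.kind == "lparen":
                depth += 1
            elif t.kind == "rparen":
                depth -= 1
            elif depth == 0 and _kw(t, "THEN"):
                break
            self.advance()
        expr_tokens = self.tokens[start:self.i]
        if not expr_tokens:
            self.fail("empty WHEN condition")
        then_tok = self.advance()  # consume THEN
        eof = Token("eof", "", then_tok.line, then_tok.column)
        return _ExprParser(expr_tokens + [eof]).parse()

    def parse_action(self, rule_id: str) -> Action:
        t = self.cur
        if t.kind != "ident" or t.text.lower() not in _ACTION_KEYWORDS:
            self.fail(
                f"expected an action ({', '.join(sorted(_ACTION_KEYWORDS))}), "
                f"found {t.text!r}"
            )
        kind = self.advance().text.lower()
        if kind == "add_item":
            item_id = f"{rule_id}_item"
            if self.cur.kind == "ident":
                item_id = self.advance().text
            text = self.expect_string("the item text")
            options: tuple[str, ...] | None = DEFAULT_OPTIONS
            priority = "normal"
            while self.cur.kind == "ident" and self.cur.text.lower() in ("guidance", "priority"):
                mod = self.advance().text.lower()
                if mod == "guidance":
                    options = None
                else:
                    lvl = self.expect_ident("a priority level").text.lower()
                    if lvl not in ("high", "normal"):
                        self.fail(f"bad priority level {lvl!r}")
                    priority = lvl
            return Action(
                kind="add_item",
                item=CheckableItem(
                    id=item_id, description=text, options=options, priority=priority
                ),
            )
        if kind == "highlight":
            item_id = self.expect_ident("an item id").text
            color = self.expect_ident("a color").text.lower()
            if color != "red":
                self.fail(f"only 'red' highlighting is defined, got {color!r}")
            return Action(kind="highlight", item_id=item_id, color="red")
        if kind == "pre_check":
            return Action(kind="pre_check", item_id=self.expect_ident("an item id").text)
        if kind == "set_priority":
            item_id = self.expect_ident("an item id").text
            level = self.expect_ident("a priority level").text.lower()
            if level not in ("high", "normal"):
                self.fail(f"bad priority level {level!r}")
            return Action(kind="set_priority", item_id=item_id, level=level)
        if kind == "attach_material":
            item_id = self.expect_ident("an item id").text
            mkind = self.expect_ident("'patient_data' or 'literature'").text.lower()
            if mkind == "patient_data":
                payload = self.expect_ident("a field name").text
            elif mkind == "literature":
                payload = self.expect_string("a citation")
            else:
                self.fail(f"unknown material kind {mkind!r}")
            return Action(
                kind="attach_material",
                item_id=item_id,
                material=SupplementaryMaterial(kind=mkind, payload=payload),
            )
        # invoke_rule
        return Action(kind="invoke_rule", rule_id=self.expect_ident("a rule id").text)


def parse_rule_dsl(text: str) -> list[Rule]:
    """Parse a rule file; raises located :class:`ParseError` on any defect."""
    if not text.strip():
        raise ParseError("empty rule file", 1, 1)
    return _DslParser(text).parse_file()


def _quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def action_to_dsl(action: Action, rule_id: str) -> str:
    if action.kind == "add_item":
        it = action.item
        parts = ["add_item"]
        if it.id != f"{rule_id}_item":
            parts.append(it.id)
        parts.append(_quote(it.description))
        if it.options is None:
            parts.append("guidance")
        if it.priority == "high":
            parts.append("priority high")
        return " ".join(parts)
    if action.kind == "highlight":
        return f"highlight {action.item_id} red"
    if action.kind == "pre_check":
        return f"pre_check {action.item_id}"
    if action.kind == "set_priority":
        return f"set_priority {action.item_id} {action.level}"
    if action.kind == "attach_material":
        m = action.material
        payload = m.payload if m.kind == "patient_data" else _quote(m.payload)
        return f"attach_material {action.item_id} {m.kind} {payload}"
    return f"invoke_rule {action.rule_id}"


def rule_to_dsl(rule: Rule) -> str:
    """Serialize one rule back to DSL text (parse/serialize round-trips)."""
    head = f"RULE {rule.id}"
    if rule.problem_id:
        head += f" FOR {rule.problem_id}"
    actions = "\n  AND ".join(action_to_dsl(a, rule.id) for a in rule.actions)
    return f"{head}\nWHEN {rule.condition.to_text()}\nTHEN {actions}"


def rules_to_dsl(rules) -> str:
    return "\n\n".join(rule_to_dsl(r) for r in rules) + "\n"
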