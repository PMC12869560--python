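"""Deterministic rule constraints applied during generation.

Rules prevent the generator emitting patterns that never occur in real
data: ``forbid-token`` zeroes a token everywhere, ``forbid-co-occurrence``
blocks two token sets from appearing in the same visit, and ``require-if``
forces consequent tokens on once the antecedent set is active.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

FORBID_TOKEN = "forbid-token"
FORBID_CO = "forbid-co-occurrence"
REQUIRE_IF = "require-if"
_KINDS = (FORBID_TOKEN, FORBID_CO, REQUIRE_IF)


class RuleError(ValueError):
    pass


@dataclass
class ConstraintRule:
    kind: str
    antecedent: frozenset[str] = frozenset()
    consequent: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise RuleError(f"unknown rule kind {self.kind!r}")
        self.antecedent = frozenset(self.antecedent)
        self.consequent = frozenset(self.consequent)
        if self.kind != FORBID_TOKEN and not self.antecedent:
            raise RuleError(f"{self.kind} rule needs an antecedent")
        if not self.consequent:
            raise RuleError("rule needs a consequent token set")


@dataclass
class ResolvedRule:
    kind: str
    antecedent: np.ndarray
    consequent: np.ndarray


def resolve_rules(rules: Sequence[ConstraintRule], vocab) -> list[ResolvedRule]:
    out = []
    for r in rules:
        try:
            ante = np.array(sorted(vocab.idx(t) for t in r.antecedent), np.int64)
            cons = np.array(sorted(vocab.idx(t) for t in r.consequent), np.int64)
        except KeyError as e:
            raise RuleError(f"rule references unknown token {e.args[0]!r}") from e
        out.append(ResolvedRule(r.kind, ante, cons))
    return out


def apply_constraints(probabilities: np.ndarray, partial_visit: Iterable[int],
                      rules: Sequence[ResolvedRule]) -> np.ndarray:
    """Mask token probabilities given tokens already active in this visit.

    Tokens whose activation would violate a rule are forced to 0;
    ``require-if`` consequents with fully active antecedents are forced
    to 1.  Contradictions (a token forced both ways) raise RuleError.
    """
    p = np.array(probabilities, dtype=float, copy=True)
    if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
        raise ValueError("probabilities must lie in [0, 1]")
    active = set(int(i) for i in partial_visit)
    forced_zero: set[int] = set()
    forced_one: set[int] = set()
    for r in rules:
        if r.kind == FORBID_TOKEN:
            forced_zero.update(int(i) for i in r.consequent)
        elif r.kind == FORBID_CO:
            # symmetric: activating either side completes the forbidden pattern
            if any(int(i) in active for i in r.antecedent):
                forced_zero.update(int(i) for i in r.consequent)
            if any(int(i) in active for i in r.consequent):
                forced_zero.update(int(i) for i in r.antecedent)
        elif r.kind == REQUIRE_IF:
            if all(int(i) in active for i in r.antecedent):
                forced_one.update(int(i) for i in r.consequent)
    clash = forced_zero & forced_one
    if clash:
        raise RuleError(f"contradictory rules force token(s) {sorted(clash)} to 0 and 1")
    if forced_zero:
        p[list(forced_zero)] = 0.0
    if forced_one:
        p[list(forced_one)] = 1.0
    return p


def rule_tokens(rules: Sequence[ResolvedRule]) -> np.ndarray:
    """All token indices mentioned by any rule (sampled sequentially)."""
    idx: set[int] = set()
    for r in rules:
        idx.update(int(i) for i in r.antecedent)
        idx.update(int(i) for i in r.consequent)
    return np.array(sorted(idx), np.int64)


def check_violations(tokenized, rules: Sequence[ConstraintRule]) -> int:
    """Exhaustive post-hoc count of rule violations in a tokenized cohort."""
    resolved = resolve_rules(rules, tokenized.vocab)
    n = 0
    for tp in tokenized.patients:
        for vec in tp.visits:
            active = set(int(i) for i in vec)
            for r in resolved:
                if r.kind == FORBID_TOKEN:
                    n += sum(int(i) in active for i in r.consequent)
                elif r.kind == FORBID_CO:
                    if any(int(i) in active for i in r.antecedent) and any(
                        int(i) in active for i in r.consequent
                    ):
                        n += 1
                elif r.kind == REQUIRE_IF:
                    if all(int(i) in active for i in r.antecedent) and not all(
                        int(i) in active for i in r.consequent
                    ):
                        n += 1
    return n


def load_rules(path) -> list[ConstraintRule]:
    """Read a declarative YAML/JSON rule file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    return [
        ConstraintRule(
            kind=r["kind"],
            antecedent=frozenset(r.get("antecedent", [])),
            consequent=frozenset(r["consequent"]),
        )
        for r in raw
    ]
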