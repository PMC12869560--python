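"""Autoregressive sampling of tokenized patients.

Generation proceeds visit-by-visit: a static/label vector is generated
first (clamped tokens for conditional generation), then visit vectors
until the end-of-record token fires or the visit cap is reached.  Within a
position, tokens are drawn in vocabulary order; the within-visit head
feeds already-drawn tokens back into the remaining logits, and two kinds
of masking are applied in the same pass: user-supplied constraint rules
and built-in structural rules (exactly one level per static or visit
categorical variable, at most one band token per discretized variable,
exactly one gap band beyond the first visit).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from ..cohort import TokenizedCohort, TokenizedPatient, TokenVocab
from .constraints import (
    FORBID_CO,
    FORBID_TOKEN,
    REQUIRE_IF,
    ConstraintRule,
    ResolvedRule,
    RuleError,
    resolve_rules,
)
from .model import GeneratorModel


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _constraint_masks(partial: np.ndarray, rules: Sequence[ResolvedRule],
                      V: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-row force-to-zero / force-to-one masks given partial visits."""
    B = partial.shape[0]
    f0 = np.zeros((B, V), bool)
    f1 = np.zeros((B, V), bool)
    for r in rules:
        if r.kind == FORBID_TOKEN:
            f0[:, r.consequent] = True
        elif r.kind == FORBID_CO:
            ante = partial[:, r.antecedent].any(1)
            cons = partial[:, r.consequent].any(1)
            f0[np.ix_(ante, r.consequent)] = True
            f0[np.ix_(cons, r.antecedent)] = True
        elif r.kind == REQUIRE_IF:
            hit = partial[:, r.antecedent].all(1)
            f1[np.ix_(hit, r.consequent)] = True
    clash = f0 & f1
    if clash.any():
        toks = sorted(set(np.nonzero(clash)[1].tolist()))
        raise RuleError(f"contradictory rules force token(s) {toks} to 0 and 1")
    return f0, f1


class _SlotPlan:
    """Vocabulary partitioned into ordered draw slots.

    A slot is either a structural group (one field's level/band tokens,
    drawn as a categorical) or a single free token (drawn as a Bernoulli);
    slots are visited in vocabulary order so the within-visit head always
    conditions on earlier draws.
    """

    def __init__(self, vocab: TokenVocab, kinds_groups: dict, free_kinds: tuple):
        grouped: dict[int, tuple[str, list[int]]] = {}
        for f, idxs in kinds_groups.items():
            grouped[min(idxs)] = (f, sorted(idxs))
        free = [i for i, t in enumerate(vocab.tokens)
                if t.kind in free_kinds and not any(
                    i in g[1] for g in grouped.values())]
        slots: list[tuple[str, object]] = []
        taken = set()
        for start in sorted(grouped):
            f, idxs = grouped[start]
            slots.append(("group", (f, np.asarray(idxs, np.int64))))
            taken.update(idxs)
        for i in free:
            if i not in taken:
                slots.append(("token", i))
        slots.sort(key=lambda s: s[1][1][0] if s[0] == "group" else s[1])
        self.slots = slots


def sample_patients(
    model: GeneratorModel,
    vocab: TokenVocab,
    n: int,
    rng_seed: int = 0,
    rules: Optional[Sequence[ConstraintRule]] = None,
    condition_labels: Optional[Sequence[str]] = None,
    temperature: float = 1.0,
    batch_size: int = 512,
) -> TokenizedCohort:
    """Sample ``n`` tokenized patients; deterministic given ``rng_seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    model.check_vocab(vocab)
    rng = np.random.default_rng(rng_seed)
    resolved = resolve_rules(rules or [], vocab)

    clamp_idx: list[int] = []
    for name in condition_labels or []:
        i = vocab.index.get(name)
        if i is None:
            raise ValueError(f"unknown condition token {name!r}")
        if vocab[i].kind not in ("label", "static_cat", "static_band"):
            raise ValueError(f"{name!r} is not a patient-label token")
        clamp_idx.append(i)

    V = len(vocab)
    Wm = model.net.win_matrix()
    static_plan = _SlotPlan(vocab, vocab.static_groups(), ("label",))
    visit_plan = _SlotPlan(vocab, vocab.visit_groups(), ("code",))
    gap_fields = {f for f, idxs in vocab.visit_groups().items()
                  if vocab[idxs[0]].kind == "gap"}
    exactly_one_kinds = {"static_cat", "static_band", "visit_cat", "gap"}
    max_visits = model.config.max_sequence_length - 3

    def draw_position(base_logits: np.ndarray, plan: _SlotPlan,
                      rows: np.ndarray, clamp: Sequence[int] = (),
                      skip_fields: frozenset = frozenset(),
                      preset: Sequence[int] = ()) -> np.ndarray:
        """Sequential slot draws for the active rows; returns (B, V).

        ``preset`` tokens (e.g. the end-of-visit marker, structurally known
        to be active) are set before any draw so their learned coupling
        conditions every draw, matching teacher forcing.
        """
        B = base_logits.shape[0]
        vec = np.zeros((B, V), np.float32)
        # within-visit head contribution, updated incrementally per draw
        contrib = np.zeros((B, V), np.float32) if Wm is not None else None
        for fixed in (clamp, preset):
            if len(fixed):
                vec[np.ix_(rows, np.asarray(fixed))] = 1.0
                if contrib is not None:
                    contrib[rows] += Wm[np.asarray(fixed)].sum(0)
        for slot_kind, payload in plan.slots:
            if rows.size == 0:
                break
            logits = base_logits[rows] / temperature
            if contrib is not None:
                logits = logits + contrib[rows] / temperature
            f0, f1 = _constraint_masks(vec[rows], resolved, V)
            probs = _sigmoid(logits)
            probs[f0] = 0.0
            probs[f1] = 1.0
            if slot_kind == "group":
                fieldname, idxs = payload
                if fieldname in skip_fields:
                    continue
                if any(i in clamp for i in idxs):
                    continue  # clamped level already set
                kind = vocab[idxs[0]].kind
                # group tokens are mutually exclusive, so their Bernoulli
                # marginals form a multinomial: P(level k) = p_k, and for
                # band groups the leftover 1 - sum(p) is the missing mass
                pk = np.clip(probs[:, idxs], 0.0, 1.0)
                tot = pk.sum(1, keepdims=True)
                if kind in exactly_one_kinds:
                    pk = pk / np.maximum(tot, 1e-12)
                else:
                    over = tot[:, 0] > 1.0
                    pk[over] = pk[over] / tot[over]
                u = rng.uniform(size=(rows.size, 1))
                cum = np.cumsum(pk, 1)
                choice = (u > cum).sum(1)
                sel = choice < len(idxs)  # beyond the last level: missing
                if kind in exactly_one_kinds:
                    choice = np.minimum(choice, len(idxs) - 1)
                    sel = tot[:, 0] > 1e-12  # fully masked group stays empty
                chosen = idxs[choice[sel]]
                vec[rows[sel], chosen] = 1.0
                if contrib is not None and sel.any():
                    contrib[rows[sel]] += Wm[chosen]
            else:
                i = payload
                if i in clamp:
                    continue
                draws = rng.uniform(size=rows.size) < probs[:, i]
                vec[rows[draws], i] = 1.0
                if contrib is not None and draws.any():
                    contrib[rows[draws]] += Wm[i]
        # require-if closure: antecedents completed by later draws
        for _ in range(len(resolved)):
            f0, f1 = _constraint_masks(vec, resolved, V)
            need = f1 & (vec == 0)
            if not need[rows].any():
                break
            vec[need] = 1.0
        return vec

    patients: list[TokenizedPatient] = []
    for start in range(0, n, batch_size):
        B = min(batch_size, n - start)
        X = np.zeros((B, 1, V), np.float32)
        X[:, 0, vocab.sor] = 1.0

        base = model.net.forward(X)[:, -1]
        lab = draw_position(base, static_plan, np.arange(B), clamp=clamp_idx)
        X = np.concatenate([X, lab[:, None]], axis=1)
        clean_visits: list[np.ndarray] = []

        done = np.zeros(B, bool)
        for t in range(max_visits + 1):
            base = model.net.forward(X)[:, -1]
            vec = np.zeros((B, V), np.float32)
            if t == 0:
                stop = np.zeros(B, bool)  # at least one visit
            elif t == max_visits:
                stop = ~done
            else:
                p_eor = _sigmoid(base[:, vocab.eor] / temperature)
                stop = (~done) & (rng.uniform(size=B) < p_eor)
            vec[stop, vocab.eor] = 1.0
            rows = np.nonzero(~done & ~stop)[0]
            if rows.size:
                skip = frozenset(gap_fields) if t == 0 else frozenset()
                body = draw_position(base, visit_plan, rows, skip_fields=skip,
                                     preset=(vocab.eov,))
                vec[rows] = body[rows]
            done |= stop
            clean_visits.append(vec.copy())
            # the static/label vector conditions every subsequent position
            ctx = np.clip(vec + lab, 0.0, 1.0)
            ctx[stop] = vec[stop]  # end-of-record rows keep the plain marker
            X = np.concatenate([X, ctx[:, None]], axis=1)
            if done.all():
                break

        for b in range(B):
            label_idx = np.nonzero(X[b, 1])[0].astype(np.int64)
            visits = []
            for vec_t in clean_visits:
                act = np.nonzero(vec_t[b])[0].astype(np.int64)
                if act.size == 0 or vocab.eor in act:
                    break
                visits.append(act)
            patients.append(TokenizedPatient(f"S{start + b:06d}", label_idx, visits))
    return TokenizedCohort(vocab, patients)
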