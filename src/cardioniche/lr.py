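"""Modified ligand-receptor scoring with enzyme/receptor surrogate pairs.

Where a mediator is a small molecule rather than a gene product (adrenergic
and cholinergic neurotransmission), its rate-limiting synthesis enzyme
stands in for the ligand: TH (catecholamine synthesis) pairs with the beta-1
adrenergic receptor ADRB1, CHAT (acetylcholine synthesis) with the M2
muscarinic receptor CHRM2.

The score between an ordered (sender state, receiver state) pair for a
surrogate pair (enzyme e, receptor r) is the mean of the two mean
expressions,

    score = (mean_expr(e, sender) + mean_expr(r, receiver)) / 2,

gated by an expression-fraction filter: the score is 0 unless at least
``min_frac`` (default 10%) of the sender's cells express the enzyme AND at
least ``min_frac`` of the receiver's cells express the receptor. A product
form ``sqrt`` -free alternative (mean_e * mean_r) is available via
``form="product"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from cardioniche.profiles import StateProfileMatrix

DEFAULT_PAIRS = [
    ("TH", "ADRB1", "adrenergic"),
    ("CHAT", "CHRM2", "cholinergic"),
]


@dataclass(frozen=True)
class SurrogatePair:
    """An enzyme-or-ligand gene on the sender side paired with a receptor gene."""

    sender_gene: str
    receiver_gene: str
    label: str = ""


def lr_score(
    profiles: StateProfileMatrix,
    pairs: list[SurrogatePair],
    senders: list[str],
    receivers: list[str],
    min_frac: float = 0.1,
    form: str = "mean",
) -> pd.DataFrame:
    """Score every (sender state, receiver state, pair) combination.

    Returns a table with columns sender_state, receiver_state, pair,
    sender_gene, receiver_gene, expressed_flag and score. The flag is true
    iff both sides clear the ``min_frac`` expressing-fraction gate; the
    score is 0 whenever the flag is false.
    """
    if form not in ("mean", "product"):
        raise ValueError(f"unknown score form {form!r}")
    genes = set(profiles.genes)
    states = set(profiles.states)
    for p in pairs:
        for g in (p.sender_gene, p.receiver_gene):
            if g not in genes:
                raise KeyError(f"gene {g!r} not in the profile gene universe")
    for s in list(senders) + list(receivers):
        if s not in states:
            raise KeyError(f"state {s!r} not in the profiles")

    rows = []
    for pair in pairs:
        for sender in senders:
            for receiver in receivers:
                frac_s = profiles.frac_expr.loc[pair.sender_gene, sender]
                frac_r = profiles.frac_expr.loc[pair.receiver_gene, receiver]
                flagged = bool(frac_s >= min_frac and frac_r >= min_frac)
                if flagged:
                    mu_s = profiles.mean_expr.loc[pair.sender_gene, sender]
                    mu_r = profiles.mean_expr.loc[pair.receiver_gene, receiver]
                    score = (mu_s + mu_r) / 2 if form == "mean" else mu_s * mu_r
                else:
                    score = 0.0
                rows.append(
                    {
                        "sender_state": sender,
                        "receiver_state": receiver,
                        "pair": pair.label or f"{pair.sender_gene}->{pair.receiver_gene}",
                        "sender_gene": pair.sender_gene,
                        "receiver_gene": pair.receiver_gene,
                        "expressed_flag": flagged,
                        "score": float(score),
                    }
                )
    return pd.DataFrame(rows)


def rank_interactions(table: pd.DataFrame) -> pd.DataFrame:
    """Sort by descending score (stable) and attach dense ranks; ties share a rank."""
    if table.empty:
        raise ValueError("empty interaction table")
    out = table.sort_values("score", ascending=False, kind="stable").reset_index(
        drop=True
    )
    out["rank"] = (
        out["score"].rank(method="dense", ascending=False).astype(int)
    )
    return out
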