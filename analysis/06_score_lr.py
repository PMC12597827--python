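#!/usr/bin/env python
"""Score surrogate ligand-receptor interactions between cell states.

On the synthetic gene space the enzyme/receptor surrogates are each state's
first planted marker gene, mirroring how TH->ADRB1 and CHAT->CHRM2 pair an
upstream synthesis enzyme with a downstream receptor. The planted
sender->receiver pair should top the ranking.
"""

import argparse
from pathlib import Path

from cardioniche.lr import SurrogatePair, lr_score, rank_interactions
from cardioniche.profiles import StateProfileMatrix

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--min-frac", type=float, default=0.1)
args = parser.parse_args()

profiles = StateProfileMatrix.from_csv(args.study / "profiles")
markers_per_state = 10
sender, receiver = profiles.states[0], profiles.states[-1]
pairs = [
    SurrogatePair(
        profiles.genes[profiles.states.index(sender) * markers_per_state],
        profiles.genes[profiles.states.index(receiver) * markers_per_state],
        label=f"{sender}->{receiver}",
    )
]
table = lr_score(
    profiles, pairs,
    senders=profiles.states, receivers=profiles.states,
    min_frac=args.min_frac,
)
ranked = rank_interactions(table)
ranked.to_csv(args.study / "lr_scores.csv", index=False)

top = ranked.iloc[0]
print(f"scored {len(ranked)} ordered state pairs for surrogate pair "
      f"{pairs[0].sender_gene} -> {pairs[0].receiver_gene}")
print(f"top interaction: {top['sender_state']} -> {top['receiver_state']} "
      f"(score {top['score']:.3f}); planted pair is {sender} -> {receiver}")
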