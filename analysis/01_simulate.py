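#!/usr/bin/env python
"""Simulate the synthetic study: single-cell reference, spatial sections, ISS run.

Writes everything downstream scripts consume to results/study/: the labelled
reference (10x triplet + cell metadata), one directory per spatial section
(triplet + spot positions with PCW), ground-truth proportion tables, the
150-gene ISS codebook and the simulated intensity tensor.
"""

import argparse
from pathlib import Path

import pandas as pd

from cardioniche import io as cio
from cardioniche.iss import random_codebook, write_codebook
from cardioniche.synthetic import (
    SyntheticConfig,
    generate_iss,
    generate_reference,
    generate_sections,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/study"))
args = parser.parse_args()

cfg = SyntheticConfig(seed=args.seed, n_sections=4, pcw_per_section=[5.5, 7.5, 10.0, 13.0])
out = args.out
out.mkdir(parents=True, exist_ok=True)

adata, _ = generate_reference(cfg)
cio.write_reference(out / "reference", adata)
print(f"reference: {adata.n_obs} cells x {adata.n_vars} genes, "
      f"{cfg.n_states} states ({cfg.markers_per_state} markers each)")

sections, truth = generate_sections(cfg)
meta_rows = []
for sec in sections:
    cio.write_section(out / "sections" / sec.section_id, sec)
    meta_rows.append({"section": sec.section_id, "pcw": sec.pcw})
pd.DataFrame(meta_rows).to_csv(out / "sections_meta.csv", index=False)
(out / "truth").mkdir(exist_ok=True)
for sec_id, P in truth.proportions.items():
    P.to_csv(out / "truth" / f"proportions_{sec_id}.csv")
print(f"sections: {len(sections)} x {cfg.spots_per_section} spots "
      f"({cfg.n_niches} contiguous niches), PCW {cfg.pcw_per_section}")

codebook = random_codebook(150, n_rounds=5, n_channels=5, seed=args.seed + 1)
write_codebook(codebook, out / "codebook.csv")
tensor, iss_truth = generate_iss(
    codebook, n_spots=5000, background=0.1, signal=1.0, noise_sd=0.05,
    seed=cfg.rng_streams()["iss"],
)
cio.write_signal_tensor(out / "iss_tensor.csv", tensor)
pd.DataFrame(
    {"spot_id": tensor.spot_ids, "gene": iss_truth.iss_gene_of_spot}
).to_csv(out / "truth" / "iss_genes.csv", index=False)
print(f"ISS: {tensor.n_spots} spots, 150-gene codebook, 5 rounds x 5 channels")
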