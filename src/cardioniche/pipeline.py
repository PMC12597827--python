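"""End-to-end orchestration: simulate -> profiles -> deconvolve -> codetect / decode / lrscore.

One ``RunConfig`` drives the whole synthetic study. Stages run in dependency
order, every output file is recorded in a JSON run manifest together with a
parameter echo, package/library versions, the seed and wall-clock time.
Re-running with the same config and seed reproduces all CSV outputs
bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from cardioniche import io as cio
from cardioniche.codetection import (
    DEFAULT_AGE_BOUNDS,
    DEFAULT_THRESHOLD,
    assign_age_groups,
    codetection_matrix,
    group_stability,
    niche_graph,
)
from cardioniche.deconvolution import fit_proportions, prediction_map_table
from cardioniche.iss import (
    decode_spots,
    expression_map_table,
    filter_calls,
    random_codebook,
    write_codebook,
)
from cardioniche.lr import SurrogatePair, lr_score, rank_interactions
from cardioniche.profiles import StateProfileMatrix, profiles_from_anndata
from cardioniche.synthetic import (
    SyntheticConfig,
    generate_iss,
    generate_reference,
    generate_sections,
)

log = logging.getLogger("cardioniche")

_STAGE_ORDER = ("simulate", "profiles", "deconvolve", "codetect", "decode", "lrscore")
_DEPENDS = {
    "profiles": "simulate",
    "deconvolve": "profiles",
    "codetect": "deconvolve",
    "decode": "simulate",
    "lrscore": "profiles",
}


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or missing data for an enabled stage (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Flat per-stage parameter namespace for one pipeline run.

    Defaults reproduce the study constants: co-detection threshold 0.07
    (strict), ISS minimum-quality cutoff 0.4 (strict), ligand-receptor
    expressing-fraction gate 0.1, and the three developmental age groups.
    """

    outdir: str = "runs/default"
    seed: int = 0
    stages: tuple[str, ...] = _STAGE_ORDER
    synthetic: dict = field(default_factory=dict)
    # deconvolution
    min_counts: float = 100.0
    ridge: float = 0.0
    # co-detection
    threshold: float = DEFAULT_THRESHOLD
    aggregation: str = "per_section_weighted"
    age_bounds: tuple = DEFAULT_AGE_BOUNDS
    # ISS
    iss_n_genes: int = 150
    iss_n_rounds: int = 5
    iss_n_channels: int = 5
    iss_n_spots: int = 2000
    iss_background: float = 0.1
    iss_signal: float = 1.0
    iss_noise_sd: float = 0.05
    min_quality: float = 0.4
    # ligand-receptor
    min_frac: float = 0.1
    lr_form: str = "mean"
    lr_senders: tuple[str, ...] = ()
    lr_receivers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGE_ORDER]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}")
        enabled = set(self.stages)
        for stage in self.stages:
            dep = _DEPENDS.get(stage)
            if dep is not None and dep not in enabled:
                raise ConfigError(f"stage {stage!r} requires stage {dep!r}")
        if not (0 < self.min_frac < 1):
            raise ConfigError("min_frac must be in (0, 1)")
        if self.min_quality < 0 or self.min_quality > 1:
            raise ConfigError("min_quality must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None
        return cfg

    def synthetic_config(self) -> SyntheticConfig:
        try:
            return SyntheticConfig(seed=self.seed, **self.synthetic)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid synthetic config: {exc}") from None


def run(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run manifest."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _jsonable(asdict(config)),
        "seed": config.seed,
        "versions": _versions(),
        "stages": {},
    }

    syn = config.synthetic_config()
    adata = profiles = sections = maps = truth = None

    for stage in _STAGE_ORDER:
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        outputs: list[str] = []

        if stage == "simulate":
            adata, _ = generate_reference(syn)
            sections, truth = generate_sections(syn)
            refdir = outdir / "reference"
            cio.write_reference(refdir, adata)
            outputs += [str(refdir / f) for f in ("matrix.mtx", "features.tsv", "barcodes.tsv", "cell_meta.csv")]
            for sec in sections:
                secdir = outdir / "sections" / sec.section_id
                cio.write_section(secdir, sec)
                outputs.append(str(secdir / "matrix.mtx"))
            for sec_id, P in truth.proportions.items():
                p = outdir / "truth" / f"proportions_{sec_id}.csv"
                p.parent.mkdir(parents=True, exist_ok=True)
                P.to_csv(p)
                outputs.append(str(p))

        elif stage == "profiles":
            profiles = profiles_from_anndata(adata)
            prefix = outdir / "profiles"
            profiles.to_csv(prefix)
            outputs += [f"{prefix}_{k}.csv" for k in ("mean_expr", "mean_linear", "frac_expr", "n_cells")]

        elif stage == "deconvolve":
            maps = [
                fit_proportions(
                    sec, profiles, min_counts=config.min_counts, ridge=config.ridge
                )
                for sec in sections
            ]
            for m in maps:
                p = outdir / "proportions" / f"{m.section_id}.csv"
                p.parent.mkdir(parents=True, exist_ok=True)
                m.proportions.to_csv(p)
                outputs.append(str(p))
                longp = outdir / "proportions" / f"{m.section_id}_map.csv"
                prediction_map_table(m, m.states).to_csv(longp, index=False)
                outputs.append(str(longp))

        elif stage == "codetect":
            matrix = codetection_matrix(maps, aggregation=config.aggregation)
            matrix.scores.to_csv(outdir / "codetection_scores.csv")
            outputs.append(str(outdir / "codetection_scores.csv"))
            G = niche_graph(matrix, threshold=config.threshold)
            edges = pd.DataFrame(
                [
                    {"state_a": a, "state_b": b, "score": d["score"]}
                    for a, b, d in sorted(G.edges(data=True))
                ]
            )
            edges.to_csv(outdir / "niche_edges.csv", index=False)
            outputs.append(str(outdir / "niche_edges.csv"))
            nx.write_graphml(G, outdir / "niche_graph.graphml")
            outputs.append(str(outdir / "niche_graph.graphml"))
            manifest["codetect_summary"] = {
                "n_edges": G.number_of_edges(),
                "n_states": G.number_of_nodes(),
            }
            try:
                partition = assign_age_groups(maps, bounds=config.age_bounds)
                present = set(partition.assignment.values())
                if len(present) >= 2:
                    _, report = group_stability(
                        maps,
                        partition.restrict(present),
                        threshold=config.threshold,
                        aggregation=config.aggregation,
                    )
                    report.to_csv(outdir / "stability_report.csv", index=False)
                    outputs.append(str(outdir / "stability_report.csv"))
            except ValueError as exc:
                log.warning("stability report skipped: %s", exc)

        elif stage == "decode":
            codebook = random_codebook(
                config.iss_n_genes,
                n_rounds=config.iss_n_rounds,
                n_channels=config.iss_n_channels,
                seed=np.random.default_rng(
                    np.random.SeedSequence(config.seed).spawn(4)[3]
                ),
            )
            write_codebook(codebook, outdir / "codebook.csv")
            outputs.append(str(outdir / "codebook.csv"))
            tensor, iss_truth = generate_iss(
                codebook,
                n_spots=config.iss_n_spots,
                background=config.iss_background,
                signal=config.iss_signal,
                noise_sd=config.iss_noise_sd,
                seed=syn.rng_streams()["iss"],
            )
            calls = decode_spots(tensor, codebook)
            kept = filter_calls(calls, min_quality_threshold=config.min_quality)
            calls.to_csv(outdir / "spot_calls.csv", index=False)
            kept.to_csv(outdir / "spot_calls_filtered.csv", index=False)
            expression_map_table(kept).to_csv(outdir / "expression_map.csv", index=False)
            truth_dir = outdir / "truth"
            truth_dir.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(
                {"spot_id": calls["spot_id"], "gene": iss_truth.iss_gene_of_spot}
            ).to_csv(truth_dir / "iss_genes.csv", index=False)
            outputs += [
                str(outdir / f)
                for f in ("spot_calls.csv", "spot_calls_filtered.csv", "expression_map.csv")
            ]
            planted = pd.Series(
                iss_truth.iss_gene_of_spot, index=calls["spot_id"].to_numpy()
            )
            manifest["decode_summary"] = {
                "n_spots": int(len(calls)),
                "n_retained": int(len(kept)),
                "accuracy_retained": float(
                    (kept["gene"].to_numpy() == planted.loc[kept["spot_id"]].to_numpy()).mean()
                )
                if len(kept)
                else float("nan"),
            }

        elif stage == "lrscore":
            senders = list(config.lr_senders) or [profiles.states[0]]
            receivers = list(config.lr_receivers) or [profiles.states[-1]]
            pairs = _synthetic_surrogate_pairs(syn, senders, receivers)
            table = lr_score(
                profiles,
                pairs,
                senders=profiles.states,
                receivers=profiles.states,
                min_frac=config.min_frac,
                form=config.lr_form,
            )
            ranked = rank_interactions(table)
            ranked.to_csv(outdir / "lr_scores.csv", index=False)
            outputs.append(str(outdir / "lr_scores.csv"))

        manifest["stages"][stage] = {"outputs": sorted(outputs)}

    manifest["wall_clock_s"] = round(time.time() - t0, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _synthetic_surrogate_pairs(
    syn: SyntheticConfig, senders: list[str], receivers: list[str]
) -> list[SurrogatePair]:
    """Surrogate pairs on synthetic gene space: first marker of sender/receiver state."""
    state_idx = {s: i for i, s in enumerate(syn.state_names)}
    pairs = []
    for s in senders:
        for r in receivers:
            e = syn.gene_names[state_idx[s] * syn.markers_per_state]
            rec = syn.gene_names[state_idx[r] * syn.markers_per_state]
            pairs.append(SurrogatePair(e, rec, label=f"{s}->{r}"))
    return pairs


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _versions() -> dict:
    from importlib.metadata import version

    import cardioniche

    out = {"cardioniche": cardioniche.__version__}
    for dist in ("numpy", "scipy", "pandas", "anndata", "networkx"):
        try:
            out[dist] = version(dist)
        except Exception:  # pragma: no cover - metadata missing
            out[dist] = "unknown"
    return out
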