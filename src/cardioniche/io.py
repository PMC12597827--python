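"""Readers and writers for the on-disk exchange formats.

Count matrices travel as the 10x-style Matrix Market triplet
(``matrix.mtx`` genes x cells, ``features.tsv``, ``barcodes.tsv``),
cell metadata as a CSV with columns ``barcode,state,donor,pcw``, spot
positions as ``barcode,section,x,y``, and ISS intensities as a long-format
CSV ``spot_id,x,y,round,channel,intensity`` (0-based round and channel).
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from cardioniche.deconvolution import SpatialSection
from cardioniche.iss import SignalTensor


def write_10x_triplet(outdir, X, gene_ids, barcodes) -> None:
    """Write a cells x genes matrix as the genes x cells 10x triplet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    M = sparse.csr_matrix(np.asarray(X).T)
    spio.mmwrite(outdir / "matrix.mtx", M)
    pd.Series(list(gene_ids)).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(list(barcodes)).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )


def read_10x_triplet(indir) -> ad.AnnData:
    """Read a 10x triplet directory into an AnnData (cells x genes)."""
    indir = Path(indir)
    M = spio.mmread(indir / "matrix.mtx").tocsr().T  # -> cells x genes
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    return ad.AnnData(
        X=M.tocsr(),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def write_reference(outdir, adata: ad.AnnData) -> None:
    """Write a labelled single-cell reference: triplet + cell metadata CSV."""
    outdir = Path(outdir)
    write_10x_triplet(outdir, adata.X, list(adata.var_names), list(adata.obs_names))
    meta = adata.obs[["state", "donor", "pcw"]].copy()
    meta.index.name = "barcode"
    meta.to_csv(outdir / "cell_meta.csv")


def read_reference(indir) -> ad.AnnData:
    indir = Path(indir)
    adata = read_10x_triplet(indir)
    meta = pd.read_csv(indir / "cell_meta.csv", index_col="barcode")
    adata.obs = meta.loc[adata.obs_names]
    return adata


def write_section(outdir, section: SpatialSection) -> None:
    """Write one spatial section: triplet + spot-position CSV (with section and pcw)."""
    outdir = Path(outdir)
    write_10x_triplet(outdir, section.counts, section.gene_ids, section.spot_ids)
    pos = pd.DataFrame(
        {
            "barcode": section.spot_ids,
            "section": section.section_id,
            "x": section.coords[:, 0],
            "y": section.coords[:, 1],
            "pcw": section.pcw,
        }
    )
    pos.to_csv(outdir / "positions.csv", index=False)


def read_section(indir) -> SpatialSection:
    indir = Path(indir)
    adata = read_10x_triplet(indir)
    pos = pd.read_csv(indir / "positions.csv").set_index("barcode")
    pos = pos.loc[list(adata.obs_names)]
    return SpatialSection(
        counts=np.asarray(adata.X.todense()),
        gene_ids=list(adata.var_names),
        spot_ids=list(adata.obs_names),
        coords=pos[["x", "y"]].to_numpy(),
        section_id=str(pos["section"].iloc[0]),
        pcw=float(pos["pcw"].iloc[0]),
    )


def write_signal_tensor(path, tensor: SignalTensor) -> None:
    """Write ISS intensities as long-format CSV (spot_id,x,y,round,channel,intensity)."""
    n_spots, n_rounds, n_channels = tensor.intensities.shape
    spot_idx, rounds, channels = np.meshgrid(
        np.arange(n_spots), np.arange(n_rounds), np.arange(n_channels), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "spot_id": np.asarray(tensor.spot_ids)[spot_idx.ravel()],
            "x": tensor.x[spot_idx.ravel()],
            "y": tensor.y[spot_idx.ravel()],
            "round": rounds.ravel(),
            "channel": channels.ravel(),
            "intensity": tensor.intensities.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_signal_tensor(path) -> SignalTensor:
    df = pd.read_csv(path)
    spots = df["spot_id"].drop_duplicates().tolist()
    n_rounds = int(df["round"].max()) + 1
    n_channels = int(df["channel"].max()) + 1
    pos = {s: i for i, s in enumerate(spots)}
    I = np.zeros((len(spots), n_rounds, n_channels))
    I[df["spot_id"].map(pos), df["round"], df["channel"]] = df["intensity"]
    first = df.drop_duplicates("spot_id").set_index("spot_id")
    return SignalTensor(
        intensities=I,
        x=first.loc[spots, "x"].to_numpy(),
        y=first.loc[spots, "y"].to_numpy(),
        spot_ids=[str(s) for s in spots],
    )
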