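"""Combinatorial ISS decoding, quality scoring and filtering.

In situ sequencing encodes each target gene as a barcode: one fluorescence
channel per imaging round. A per-round max-channel decoder reads the barcode
off a spot's intensity tensor by taking, in every round, the channel with the
highest intensity. Each round also yields a quality score -- the winning
channel's intensity normalized by the round's total intensity (L1 rule):

    q_r = I_max,r / sum_c I_c,r

so a clean one-hot round scores 1 and a perfectly uniform round scores
1/n_channels. Two per-spot summaries are kept: the mean quality across
rounds and the minimum quality (the worst round). Calls are retained only
when the minimum quality is strictly above a threshold (default 0.4) and the
barcode matches the codebook exactly.

With C channels, uniform background b added to signal s gives
q = (s + b) / (s + C b), strictly decreasing in b -- the monotonicity that
makes the minimum-quality filter discriminative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNDECODED = ""


@dataclass
class Codebook:
    """Mapping from each target gene to its per-round channel assignment.

    ``code[gene]`` is a tuple of 0-based channel indices, one per round.
    Codes must be unique across genes and channel indices must be in range.
    """

    genes: list[str]
    n_rounds: int
    n_channels: int
    code: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("codebook is empty")
        if set(self.genes) != set(self.code):
            raise ValueError("gene list and code table disagree")
        seen: dict[tuple[int, ...], str] = {}
        for gene, code in self.code.items():
            if len(code) != self.n_rounds:
                raise ValueError(
                    f"gene {gene!r} has {len(code)} rounds, expected {self.n_rounds}"
                )
            if any(c < 0 or c >= self.n_channels for c in code):
                raise ValueError(f"gene {gene!r} has an out-of-range channel index")
            if code in seen:
                raise ValueError(
                    f"duplicate barcode {code} shared by {seen[code]!r} and {gene!r}"
                )
            seen[code] = gene

    def lookup(self) -> dict[tuple[int, ...], str]:
        """Barcode -> gene inverse mapping."""
        return {code: gene for gene, code in self.code.items()}


@dataclass
class SignalTensor:
    """Raw per-spot ISS intensities: spots x rounds x channels, with planar coordinates."""

    intensities: np.ndarray
    x: np.ndarray
    y: np.ndarray
    spot_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be spots x rounds x channels")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        if np.any(self.intensities < 0):
            raise ValueError("intensities contain negative values")
        n = self.intensities.shape[0]
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != n or len(self.y) != n:
            raise ValueError("coordinate length does not match number of spots")
        if not self.spot_ids:
            self.spot_ids = [f"spot_{i}" for i in range(n)]

    @property
    def n_spots(self) -> int:
        return self.intensities.shape[0]


def random_codebook(
    n_genes: int,
    n_rounds: int = 5,
    n_channels: int = 5,
    seed: int | np.random.Generator = 0,
    gene_prefix: str = "gene",
) -> Codebook:
    """Draw ``n_genes`` distinct one-hot-per-round barcodes uniformly at random.

    Requires n_genes <= n_channels ** n_rounds (the code space size).
    """
    space = n_channels**n_rounds
    if n_genes > space:
        raise ValueError(
            f"cannot place {n_genes} unique codes in a space of {space}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(space, size=n_genes, replace=False)
    codes = {}
    for i, flat in enumerate(sorted(int(v) for v in chosen)):
        digits = []
        for _ in range(n_rounds):
            digits.append(flat % n_channels)
            flat //= n_channels
        codes[f"{gene_prefix}_{i:03d}"] = tuple(digits)
    return Codebook(
        genes=list(codes), n_rounds=n_rounds, n_channels=n_channels, code=codes
    )


def load_codebook(path) -> Codebook:
    """Read a codebook CSV with columns ``gene, round_1..round_R`` (0-based channels).

    The number of channels is inferred as ``max index + 1`` unless a
    ``# n_channels=C`` value is carried in a column named ``n_channels``.
    """
    df = pd.read_csv(path)
    round_cols = sorted(
        (c for c in df.columns if c.startswith("round_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if "gene" not in df.columns or not round_cols:
        raise ValueError("codebook CSV needs a 'gene' column and round_1..round_R columns")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene {dup!r} in codebook")
    if "n_channels" in df.columns:
        n_channels = int(df["n_channels"].iloc[0])
    else:
        n_channels = int(df[round_cols].to_numpy().max()) + 1
    code = {
        str(row["gene"]): tuple(int(row[c]) for c in round_cols)
        for _, row in df.iterrows()
    }
    return Codebook(
        genes=list(code), n_rounds=len(round_cols), n_channels=n_channels, code=code
    )


def write_codebook(codebook: Codebook, path) -> None:
    rows = []
    for gene in codebook.genes:
        row = {"gene": gene}
        for r, ch in enumerate(codebook.code[gene], start=1):
            row[f"round_{r}"] = ch
        row["n_channels"] = codebook.n_channels
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def decode_spots(tensor: SignalTensor, codebook: Codebook) -> pd.DataFrame:
    """Per-round max-channel decoding with L1 quality scores.

    Returns a spot-call table with one row per spot: coordinates, the decoded
    barcode (dash-joined channel indices), the called gene (empty string when
    the barcode has no codebook entry), per-spot ``mean_quality`` and
    ``min_quality``, and a ``tie_flag`` marking spots where an argmax tie or
    an all-zero round forced a convention (ties break to the lowest channel
    index; all-zero rounds score the uniform quality 1/n_channels).
    """
    I = tensor.intensities
    n_spots, n_rounds, n_channels = I.shape
    if n_rounds != codebook.n_rounds or n_channels != codebook.n_channels:
        raise ValueError(
            f"tensor shape {(n_rounds, n_channels)} does not match codebook "
            f"{(codebook.n_rounds, codebook.n_channels)}"
        )

    winners = I.argmax(axis=2)  # ties -> lowest index, numpy convention
    round_totals = I.sum(axis=2)
    max_int = np.take_along_axis(I, winners[:, :, None], axis=2)[:, :, 0]

    zero_rounds = round_totals == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        quality = np.where(zero_rounds, 1.0 / n_channels, max_int / np.where(round_totals == 0, 1.0, round_totals))

    # a tie: more than one channel attains the round maximum
    n_at_max = (I == max_int[:, :, None]).sum(axis=2)
    tied = (n_at_max > 1) | zero_rounds

    lookup = codebook.lookup()
    barcodes = [tuple(int(c) for c in row) for row in winners]
    genes = [lookup.get(bc, UNDECODED) for bc in barcodes]

    table = pd.DataFrame(
        {
            "spot_id": tensor.spot_ids,
            "x": tensor.x,
            "y": tensor.y,
            "gene": genes,
            "barcode": ["-".join(str(c) for c in bc) for bc in barcodes],
            "mean_quality": quality.mean(axis=1),
            "min_quality": quality.min(axis=1),
            "tie_flag": tied.any(axis=1),
        }
    )
    for r in range(n_rounds):
        table[f"quality_round_{r + 1}"] = quality[:, r]
    return table


def filter_calls(
    table: pd.DataFrame, min_quality_threshold: float = 0.4
) -> pd.DataFrame:
    """Retain calls with minimum quality strictly over the threshold and a decoded gene.

    A spot whose worst round scores exactly at the threshold is removed.
    """
    if table.empty:
        return table.copy()
    decoded = table["gene"] != UNDECODED
    high_quality = table["min_quality"] > min_quality_threshold
    kept = table[decoded & high_quality].reset_index(drop=True)
    kept.attrs["n_removed_undecoded"] = int((~decoded).sum())
    kept.attrs["n_removed_low_quality"] = int((decoded & ~high_quality).sum())
    return kept


def expression_map(table: pd.DataFrame) -> tuple[dict[str, np.ndarray], pd.Series]:
    """Assemble per-gene spatial expression maps from a (filtered) call table.

    Returns ``(positions, counts)`` where ``positions[gene]`` is an (n, 2)
    array of (x, y) coordinates and ``counts`` the per-gene call counts.
    Undecoded rows, if present, are dropped.
    """
    calls = table[table["gene"] != UNDECODED]
    positions = {
        gene: grp[["x", "y"]].to_numpy(dtype=float)
        for gene, grp in calls.groupby("gene", sort=True)
    }
    counts = calls["gene"].value_counts().sort_index()
    counts.name = "n_spots"
    return positions, counts


def expression_map_table(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format (gene, x, y) table of retained calls, for CSV export."""
    calls = table[table["gene"] != UNDECODED]
    return calls[["gene", "x", "y"]].sort_values("gene").reset_index(drop=True)
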