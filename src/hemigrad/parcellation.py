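"""Homotopic parcellation tables.

A homotopic parcellation assigns every cortical region a hemisphere
(L or R), a pair index linking it to its mirror-matched homologue in the
other hemisphere, and a functional network label (Yeo-7 by default).
Every block partition of the connectome, every asymmetry-index pairing and
every network aggregation downstream keys on this table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

YEO7_NETWORKS = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "SalienceVentralAttention",
    "Limbic",
    "Control",
    "DefaultMode",
)

_COLUMNS = ["region_id", "hemisphere", "pair_index", "network", "region_name"]


@dataclass(frozen=True)
class Parcellation:
    """A validated homotopic region table.

    The underlying frame has one row per region with columns
    ``region_id, hemisphere, pair_index, network, region_name``.
    Invariants (checked on construction): each pair index appears exactly
    once per hemisphere, and both members of a pair share a network label.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"parcellation table missing columns: {missing}")
        bad_hemi = set(df["hemisphere"].unique()) - {"L", "R"}
        if bad_hemi:
            raise ValueError(f"hemisphere labels must be L/R, got {sorted(bad_hemi)}")
        n_pairs = self.n_pairs
        for hemi in ("L", "R"):
            idx = df.loc[df["hemisphere"] == hemi, "pair_index"].to_numpy()
            if len(idx) != n_pairs or set(idx) != set(range(n_pairs)):
                raise ValueError(
                    f"pair_index must appear exactly once per hemisphere; "
                    f"hemisphere {hemi} violates this"
                )
        nets = df.groupby("pair_index")["network"].nunique()
        if (nets != 1).any():
            bad = nets[nets != 1].index.tolist()
            raise ValueError(f"homotopic pairs with conflicting network labels: {bad}")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def n_pairs(self) -> int:
        return len(self.table) // 2

    @property
    def networks(self) -> list[str]:
        """Unique network labels in first-appearance (pair-index) order."""
        by_pair = self.pair_networks
        seen: dict[str, None] = {}
        for n in by_pair:
            seen.setdefault(n, None)
        return list(seen)

    @property
    def pair_networks(self) -> np.ndarray:
        """Network label of each homotopic pair, indexed by pair_index."""
        left = self.table[self.table["hemisphere"] == "L"]
        return (
            left.sort_values("pair_index")["network"].to_numpy()
        )

    def hemisphere_indices(self, hemisphere: str) -> np.ndarray:
        """Row positions of one hemisphere's regions, ordered by pair_index."""
        if hemisphere not in ("L", "R"):
            raise ValueError("hemisphere must be 'L' or 'R'")
        df = self.table.reset_index(drop=True)
        sub = df[df["hemisphere"] == hemisphere].sort_values("pair_index")
        return sub.index.to_numpy()

    def region_ids(self) -> list[str]:
        return self.table["region_id"].tolist()


def make_parcellation(n_pairs: int, n_networks: int) -> Parcellation:
    """Build a homotopic parcellation of ``2 * n_pairs`` regions.

    Pairs are assigned to ``n_networks`` contiguous, near-even network
    blocks. With ``n_networks == 7`` the canonical Yeo-7 labels are used;
    otherwise labels are ``Net1 .. NetK``.
    """
    if n_pairs < 1 or n_networks < 1:
        raise ValueError("n_pairs and n_networks must be positive")
    if n_networks > n_pairs:
        raise ValueError("n_networks cannot exceed n_pairs")
    if n_networks == 7:
        labels = YEO7_NETWORKS
    else:
        labels = tuple(f"Net{i + 1}" for i in range(n_networks))
    # near-even contiguous partition of pair indices into networks
    net_of_pair = (np.arange(n_pairs) * n_networks) // n_pairs
    rows = []
    for hemi in ("L", "R"):
        for p in range(n_pairs):
            net = labels[net_of_pair[p]]
            rows.append(
                {
                    "region_id": f"{hemi}_{p:03d}",
                    "hemisphere": hemi,
                    "pair_index": p,
                    "network": net,
                    "region_name": f"{net}_{hemi}{p:03d}",
                }
            )
    return Parcellation(pd.DataFrame(rows, columns=_COLUMNS))


def read_parcellation(path) -> Parcellation:
    """Read a parcellation TSV (columns as in :data:`_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return Parcellation(df[_COLUMNS])


def write_parcellation(parc: Parcellation, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        parc.table.to_csv(fh, sep="\t", index=False)
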