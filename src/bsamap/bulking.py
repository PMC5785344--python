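"""Constitution of high/low phenotypic bulks from a phenotype table.

The bulks are the two tails of the amylose distribution: the high-amylose
bulk (HAB) takes the n largest phenotypes, the low-amylose bulk (LAB) the n
smallest.  Ties are broken by ascending sample id so the selection is
deterministic and invariant to input row order.  DNA pooling downstream
assumes equal per-individual contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BulkDefinition:
    label: str                      # "HAB" or "LAB"
    members: tuple[str, ...]
    ac_range: tuple[float, float]   # (min %, max %)


def select_bulks(phenotypes: pd.DataFrame, n_per_bulk: int = 10,
                 id_col: str = "sample", ac_col: str = "ac",
                 ) -> tuple[BulkDefinition, BulkDefinition]:
    """Pick the two phenotypic tails as bulks.

    Returns (HAB, LAB).  Requires at least ``2 * n_per_bulk`` phenotyped
    individuals with unique ids and finite phenotype values.
    """
    if n_per_bulk < 1:
        raise ValueError("n_per_bulk must be >= 1")
    df = phenotypes[[id_col, ac_col]].copy()
    if df[id_col].duplicated().any():
        dupes = df.loc[df[id_col].duplicated(), id_col].tolist()
        raise ValueError(f"duplicated sample ids: {dupes}")
    if not np.isfinite(df[ac_col]).all():
        raise ValueError("non-finite phenotype values")
    if len(df) < 2 * n_per_bulk:
        raise ValueError(
            f"need >= {2 * n_per_bulk} phenotyped individuals, got {len(df)}")

    # one global (ac, id) ranking: LAB = bottom n, HAB = top n.  The shared
    # id tie-break keeps the two tails disjoint even when phenotypes tie.
    asc = df.sort_values([ac_col, id_col], ascending=[True, True])
    lab_rows = asc.head(n_per_bulk)
    hab_rows = asc.tail(n_per_bulk)

    def _bulk(label: str, rows: pd.DataFrame) -> BulkDefinition:
        ac = rows[ac_col].to_numpy(dtype=float)
        return BulkDefinition(label, tuple(sorted(rows[id_col])),
                              (float(ac.min()), float(ac.max())))

    hab, lab = _bulk("HAB", hab_rows), _bulk("LAB", lab_rows)
    overlap = set(hab.members) & set(lab.members)
    if overlap:
        raise ValueError(f"bulks overlap (population too small): {sorted(overlap)}")
    return hab, lab


def bulk_table(hab: BulkDefinition, lab: BulkDefinition) -> pd.DataFrame:
    rows = [(b.label, m, b.ac_range[0], b.ac_range[1])
            for b in (hab, lab) for m in b.members]
    return pd.DataFrame(rows, columns=["bulk", "sample", "ac_min", "ac_max"])
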