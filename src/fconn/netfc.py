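"""Large-scale within- and between-network functional connectivity.

Block means are taken over the UNTHRESHOLDED Fisher-z matrix: 8 within-network
values (mean z over all unordered ROI pairs inside a network) and 28
between-network values (mean z over all pairs spanning the two networks),
compared across groups with the covariate-adjusted GLM and BH-FDR across all
36 values.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .inference import Design, compare_metrics
from .io import NETWORKS, NodeTable

logger = logging.getLogger("fconn")


def block_labels() -> list[str]:
    """Canonical 36 block names: 8 within, then 28 between in network order."""
    within = [f"within_{net}" for net in NETWORKS]
    between = [f"between_{a}_{b}" for a, b in itertools.combinations(NETWORKS, 2)]
    return within + between


def network_block_means(c: ConnectivityMatrix, nodes: NodeTable) -> pd.Series:
    """The 36 block-mean z values for one subject.

    A network with a single node has no within pair; its within value is NaN
    (flagged, not silently zero).
    """
    if c.n_nodes != nodes.n_nodes:
        raise ValueError(
            f"FC matrix has {c.n_nodes} nodes, node table {nodes.n_nodes}"
        )
    members = nodes.network_members()
    for net in NETWORKS:
        if members[net].size == 0 and nodes.n_nodes >= len(NETWORKS):
            raise ValueError(f"no nodes labelled {net}")
    z = c.z
    out = {}
    for net in NETWORKS:
        idx = members[net]
        if idx.size < 2:
            out[f"within_{net}"] = np.nan
            continue
        block = z[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, 1)
        out[f"within_{net}"] = float(block[iu].mean())
    for a, b in itertools.combinations(NETWORKS, 2):
        ia, ib = members[a], members[b]
        out[f"between_{a}_{b}"] = (
            float(z[np.ix_(ia, ib)].mean()) if ia.size and ib.size else np.nan
        )
    return pd.Series(out, index=block_labels(), name=c.subject_id)


def network_fc_table(
    fc_list: list[ConnectivityMatrix], nodes: NodeTable
) -> pd.DataFrame:
    """Subjects x 36 table of block means, indexed by subject_id."""
    rows = [network_block_means(c, nodes) for c in fc_list]
    return pd.DataFrame(rows)


def compare_network_fc(
    table: pd.DataFrame, design: Design, q: float = 0.05
) -> pd.DataFrame:
    """GLM contrast per block value, BH-FDR across all 36 tests.

    Block values flagged undefined (NaN, from single-node networks) are
    excluded from the family with a warning.
    """
    if len(table) != design.x.shape[0]:
        raise ValueError(
            f"{len(table)} table rows for {design.x.shape[0]} design rows"
        )
    defined = table.columns[table.notna().all(axis=0)]
    dropped = [c for c in table.columns if c not in set(defined)]
    if dropped:
        logger.warning("skipping undefined block value(s): %s", ", ".join(dropped))
    return compare_metrics(table[defined], design, q=q, fdr=True)
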