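"""Distance-based tree scaffold (neighbor joining).

The pipeline needs only *relative* placement — which reference anchor a
CPO-grammar candidate sits closest to — so trees are built by neighbor
joining over Kimura-corrected pairwise protein distances rather than by
maximum likelihood.  NJ is exact on additive distance matrices, which
is the module's central correctness property.
"""

from __future__ import annotations

import io
import logging
import math
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from upomine.homology import ScoringScheme, _make_aligner
from upomine.io_formats import ProteinRecord

logger = logging.getLogger(__name__)

#: Proportion of differing sites beyond which the Kimura correction is
#: undefined (1 - p - 0.2 p**2 <= 0 near p ~ 0.85).
KIMURA_P_MAX = 0.85


def kimura_correction(p: float, max_distance: float = 5.0) -> tuple[float, bool]:
    """Kimura-corrected protein distance d = -ln(1 - p - 0.2 p²).

    Returns ``(distance, capped)``; for ``p >= 0.85`` the correction is
    undefined and the distance is capped at ``max_distance``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-distance {p} outside [0, 1]")
    if p >= KIMURA_P_MAX:
        return max_distance, True
    return -math.log(1.0 - p - 0.2 * p * p), False


def protein_distance(
    a: ProteinRecord,
    b: ProteinRecord,
    scheme: ScoringScheme | None = None,
    max_distance: float = 5.0,
) -> float:
    """Kimura-corrected distance from the pairwise local alignment.

    ``p`` is the fraction of differing residue pairs over the gap-free
    aligned columns.  Zero aligned columns (no local similarity at all)
    is an error — such pairs carry no distance signal.
    """
    scheme = (scheme or ScoringScheme()).with_stats()
    aligner = _make_aligner(scheme)
    if a.residues == b.residues:
        return 0.0
    if aligner.score(a.residues, b.residues) <= 0:
        raise ValueError(f"no aligned columns between {a.id!r} and {b.id!r}")
    counts = aligner.align(a.residues, b.residues)[0].counts()
    aligned = counts.identities + counts.mismatches
    if aligned == 0:
        raise ValueError(f"no aligned columns between {a.id!r} and {b.id!r}")
    p = counts.mismatches / aligned
    d, capped = kimura_correction(p, max_distance)
    if capped:
        logger.warning(
            "distance %s-%s capped at %.1f (p=%.2f beyond Kimura domain)",
            a.id, b.id, max_distance, p,
        )
    return d


def distance_matrix(
    records: list[ProteinRecord],
    scheme: ScoringScheme | None = None,
    max_distance: float = 5.0,
) -> DistanceMatrix:
    """All-pairs Kimura distance matrix over a record collection."""
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = protein_distance(
                records[i], records[j], scheme, max_distance
            )
    return DistanceMatrix(D, [r.id for r in records])


def nj_tree(D: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch estimates are clamped to 0.

    ``n = 2`` produces the single-edge tree with the distance split
    evenly between the two leaves.
    """
    if isinstance(D, np.ndarray):
        raise TypeError("pass an skbio DistanceMatrix (ids are required)")
    ids = list(D.ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")
    if len(ids) == 2:
        d = float(D[0, 1])
        newick = f"('{ids[0]}':{d / 2:.6g},'{ids[1]}':{d / 2:.6g});"
        return TreeNode.read(io.StringIO(newick))
    return nj(D, neg_as_zero=True)


def _quote(label: str) -> str:
    if any(c in label for c in " \t()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _to_newick(node: TreeNode) -> str:
    if node.is_tip():
        s = _quote(node.name or "")
    else:
        s = "(" + ",".join(_to_newick(c) for c in node.children) + ")"
        if node.name:
            s += _quote(node.name)
    if node.length is not None:
        s += f":{node.length:.6g}"
    return s


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree as Newick with 6-significant-digit branch lengths.

    Labels containing spaces or Newick metacharacters are quoted.
    """
    with open(path, "w") as fh:
        fh.write(_to_newick(tree) + ";\n")


def read_newick(path: str | Path) -> TreeNode:
    """Parse a Newick file into an skbio TreeNode."""
    return TreeNode.read(str(path))
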