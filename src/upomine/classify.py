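"""Subfamily, superfamily and mass-class assignment.

Grammar-positive sequences are placed into the five UPO subfamilies
(I–V) by their signature motif content: for each subfamily the score is
the fraction of its signature motifs with at least one hit, and the
arg-max subfamily is assigned when the score reaches 0.5 with at least
two signature motifs matched (ties or weaker evidence stay
``unassigned``).  Sequences with the CPO grammar are not scored on
signatures; they are placed by tree proximity to reference anchors as
either the mixed peroxidase-peroxygenase (Pog) superfamily or classic
CPOs.

Independently of the family call, every sequence receives a mass class:
Group-I (short UPOs, ~29 kDa on average) below 35 kDa, Group-II (long
UPOs, ~44 kDa on average) at or above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.SeqUtils import molecular_weight as _bio_mw

from upomine.grammar import GrammarResult
from upomine.io_formats import ProteinRecord
from upomine.motifs import (
    CYS_PAIR_RULE,
    NHG_VARIANTS,
    SUBFAMILIES,
    MotifHit,
    MotifRegistry,
    matches_variant,
)

#: Average mass assumed for an unknown residue (X), in daltons.
X_RESIDUE_MASS = 110.0

WATER_MASS = 18.01528

FAMILY_LABELS = SUBFAMILIES + ("Pog", "classic_CPO", "unassigned")


@dataclass(frozen=True)
class MassClass:
    """Molecular weight in kDa with its Group-I/II threshold."""

    weight_kda: float
    uncertain: bool = False  # True when X residues were counted at the mean mass
    group_threshold_kda: float = 35.0

    def __post_init__(self) -> None:
        if self.weight_kda <= 0:
            raise ValueError("weight must be positive")


@dataclass(frozen=True)
class SubfamilyCall:
    """The final classification of one sequence."""

    record_id: str
    family: str  # I..V | Pog | classic_CPO | unassigned
    group: str  # Group-I | Group-II
    evidence: tuple[str, ...]  # motif names supporting the call
    score: float  # matched-signature fraction for the assigned family
    grammar_class: str
    all_scores: dict = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILY_LABELS:
            raise ValueError(f"unknown family label {self.family!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score outside [0, 1]")


def molecular_weight(seq: ProteinRecord, group_threshold_kda: float = 35.0) -> MassClass:
    """Average molecular weight of the intact chain, in kDa.

    Sum of anhydrous residue masses plus one water for the chain
    termini.  Unknown residues (X) are counted at a 110 Da mean residue
    mass and flagged as uncertain.
    """
    if not seq.residues:
        raise ValueError("empty sequence")
    n_x = seq.residues.count("X")
    stripped = seq.residues.replace("X", "")
    daltons = n_x * X_RESIDUE_MASS
    if stripped:
        daltons += _bio_mw(stripped, seq_type="protein")
    else:
        daltons += WATER_MASS
    return MassClass(daltons / 1000.0, uncertain=n_x > 0,
                     group_threshold_kda=group_threshold_kda)


def assign_group(mass: MassClass) -> str:
    """Group-I below the threshold, Group-II at or above it."""
    return "Group-I" if mass.weight_kda < mass.group_threshold_kda else "Group-II"


def _signature_matched(
    name: str,
    subfamily: str,
    hits_by_name: dict,
) -> bool:
    hits = hits_by_name.get(name, [])
    if not hits:
        return False
    if name == "NHG_family":
        variants = NHG_VARIANTS[subfamily]
        return any(matches_variant(h, variants) for h in hits)
    return True


def classify_subfamily(
    grammar: GrammarResult,
    hits: list[MotifHit],
    registry: MotifRegistry,
    record_id: str = "",
    *,
    group: str = "Group-I",
    min_score: float = 0.5,
    min_motifs: int = 2,
) -> SubfamilyCall:
    """Score signature motif content and assign a subfamily.

    ``hits`` holds every motif hit found on the sequence; satisfaction
    of the Cys-Cys disulfide rule is conveyed as a pseudo-hit named
    ``CYS_CYS`` (see :func:`upomine.motifs.cys_pair_evidence`).
    Sequences with the plain CPO grammar bypass subfamily scoring and
    are flagged ``needs-tree`` for Pog/classic-CPO placement.
    """
    if grammar.grammar_class == "none":
        raise ValueError("cannot classify a sequence without a grammar verdict")

    if grammar.grammar_class == "CPO_core":
        return SubfamilyCall(
            record_id=record_id,
            family="unassigned",
            group=group,
            evidence=(),
            score=0.0,
            grammar_class=grammar.grammar_class,
            flags=("needs-tree",),
        )

    hits_by_name: dict[str, list[MotifHit]] = {}
    for h in hits:
        hits_by_name.setdefault(h.motif, []).append(h)

    scores: dict[str, float] = {}
    matched: dict[str, tuple[str, ...]] = {}
    for fam in SUBFAMILIES:
        names = registry.signature_names(fam)
        got = tuple(n for n in names if _signature_matched(n, fam, hits_by_name))
        matched[fam] = got
        scores[fam] = len(got) / len(names) if names else 0.0

    best = max(scores.values())
    winners = [f for f in SUBFAMILIES if scores[f] == best]
    flags: list[str] = []
    if (
        best >= min_score
        and len(winners) == 1
        and len(matched[winners[0]]) >= min_motifs
    ):
        fam = winners[0]
        evidence = matched[fam]
        if CYS_PAIR_RULE in evidence:
            flags.append("weak-cys-evidence")
        return SubfamilyCall(
            record_id=record_id,
            family=fam,
            group=group,
            evidence=evidence,
            score=scores[fam],
            grammar_class=grammar.grammar_class,
            all_scores=scores,
            flags=tuple(flags),
        )
    if len(winners) > 1 and best >= min_score:
        flags.append("tied-scores")
    return SubfamilyCall(
        record_id=record_id,
        family="unassigned",
        group=group,
        evidence=(),
        score=0.0,
        grammar_class=grammar.grammar_class,
        all_scores=scores,
        flags=tuple(flags),
    )


def place_cpo(call: SubfamilyCall, tree, anchors: dict) -> SubfamilyCall:
    """Place a CPO-grammar sequence as Pog or classic CPO by tree proximity.

    ``tree`` is an skbio ``TreeNode`` over candidates plus anchor
    sequences; ``anchors`` maps leaf names to roles (``"pog"`` for
    MroUPO-like exemplars, ``"classic_cpo"`` for classic CPO
    exemplars).  The candidate takes the role of its nearest anchor by
    path length; exact ties go to Pog (conservative toward the
    superfamily) with a ``tie`` flag.
    """
    roles = set(anchors.values())
    missing = {"pog", "classic_cpo"} - roles
    if missing:
        raise ValueError(f"missing anchor roles: {sorted(missing)}")
    node = tree.find(call.record_id)
    best: dict[str, float] = {}
    for leaf, role in anchors.items():
        d = node.distance(tree.find(leaf))
        if role not in best or d < best[role]:
            best[role] = d
    flags = [f for f in call.flags if f != "needs-tree"]
    if best["pog"] <= best["classic_cpo"]:
        family = "Pog"
        if best["pog"] == best["classic_cpo"]:
            flags.append("tie")
    else:
        family = "classic_CPO"
    return replace(call, family=family, flags=tuple(flags))
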