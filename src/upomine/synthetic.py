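"""Seeded synthetic proteomes with planted UPO/CPO anatomies.

The generator emulates the statistical situation the mining pipeline
faces: a handful of grammar-conformant heme-thiolate peroxidase
sequences embedded in a large background of unrelated proteins.
Planted UPO sequences follow the AaeUPO coordinate template — PCP
around residue 35 (proximal Cys36), S[IL]G around 60, the distal
tripeptide around 122, SXXRXD around 130, and the Arg/Glu acid-base
pair around 189/196 — with seed-controlled jitter of ±10 positions so
that position-hardcoded consumers are caught.  Each planted sequence
carries exactly its subfamily's signature motifs: after construction
the full registry is re-scanned and any accidental motif hit outside
the planted intervals is mutated away; decoys are resampled until they
fail the core grammar.

All sampling is integer-based (``Generator.integers``), so identical
seeds give bit-identical output across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from upomine.grammar import find_core_grammar
from upomine.io_formats import CANONICAL, ProteinRecord
from upomine.motifs import (
    MotifRegistry,
    default_registry,
    parse_pattern,
    scan_registry,
)

#: AaeUPO-like anchor coordinates (1-based starts) for the planted anatomy.
TEMPLATE_ANCHORS = {"PCP": 35, "S[IL]G": 60, "distal": 122, "SXXRXD": 130, "R": 189}
TEMPLATE_SPACING = 6
TEMPLATE_LENGTH = 270
ANCHOR_JITTER = 10

#: Concrete signature-motif instantiations planted per subfamily (X
#: wildcards are filled with background letters at generation time).
SUBFAMILY_PLANTS = {
    "I": (("NHG_family", "SHG"), ("FXD", "FXD"), ("HXXF", "HXXF")),
    "II": (
        ("NHG_family", "NHG"), ("RGN", "RGN"), ("IDG", "IDG"),
        ("TXXXXXXR", "TXXXXXXR"), ("VPPLPG", "VPPLPG"), ("HXXF", "HXXF"),
    ),
    "III": (("NHG_family", "NHG"), ("G[ML]G", "GMG")),
    "IV": (
        ("NHG_family", "NHN"), ("CDA", "CDA"), ("FXXXDG", "FXXXDG"),
        ("GAAXXXYE", "GAAXXXYE"), ("HXXF", "HXXF"),
    ),
    "V": (("NHG_family", "NHG"), ("EDXXH", "EDXXH"), ("GXG", "GXG")),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic proteome.

    Defaults plant 30 UPO sequences (six per subfamily) among 500
    decoy proteins of 200–500 residues — a strain-level mutation cloud
    (3% substitutions) around one template per subfamily, each template
    ~20% diverged from the common UPO-like query.
    """

    subfamily_counts: tuple = (("I", 6), ("II", 6), ("III", 6), ("IV", 6), ("V", 6))
    pog_like: int = 0
    classic_like: int = 0
    cpo_mutation_budget: int = 12
    cpo_divergence: float = 0.45
    decoys: int = 500
    decoy_length: tuple[int, int] = (200, 500)
    background: tuple[float, ...] | None = None  # None = uniform over 20 letters
    mutation_rate: float = 0.03
    template_divergence: float = 0.20
    seed: int = 42

    def __post_init__(self) -> None:
        if any(c < 0 for _, c in self.subfamily_counts):
            raise ValueError("negative planted count")
        if self.decoys < 0 or self.pog_like < 0 or self.classic_like < 0:
            raise ValueError("negative count")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation rate outside [0, 1)")
        if self.decoy_length[0] > self.decoy_length[1] or self.decoy_length[0] < 1:
            raise ValueError("bad decoy length range")


@dataclass
class SyntheticProteome:
    """Generator output: proteome records, query/anchors, and ground truth."""

    records: list  # planted + decoys, shuffled order
    query: ProteinRecord
    anchors: dict  # anchor id -> role ("pog" | "classic_cpo")
    anchor_records: list
    truth: pd.DataFrame  # id, grammar_class, family, coords
    seed: int


# --- low-level sampling helpers -------------------------------------------


def _sample_letters(rng: np.random.Generator, n: int, alphabet: str) -> list[str]:
    idx = rng.integers(0, len(alphabet), size=n)
    return [alphabet[i] for i in idx]


def _mutation_mask(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    # integer-based Bernoulli draw for cross-platform determinism
    threshold = int(round(rate * 1_000_000))
    return rng.integers(0, 1_000_000, size=n) < threshold


def _in_intervals(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def _instantiate(pattern: str, rng: np.random.Generator, alphabet: str) -> str:
    """Concrete residue string for a pattern (wildcards filled randomly)."""
    out = []
    for cls in parse_pattern(pattern):
        if cls is None:
            out.append(alphabet[rng.integers(0, len(alphabet))])
        else:
            letters = sorted(cls)
            out.append(letters[rng.integers(0, len(letters))])
    return "".join(out)


def _extra_hits_within(
    inst: str, own_patterns: tuple[str, ...], registry: MotifRegistry
) -> int:
    """Count hits of *other* registry motifs fully inside an instance."""
    own = set(own_patterns)
    count = 0
    for entry in registry:
        if entry.kind != "pattern":
            continue
        for p in entry.patterns:
            if p in own:
                continue
            classes = parse_pattern(p)
            L = len(classes)
            for start in range(len(inst) - L + 1):
                if all(
                    cls is None or inst[start + k] in cls
                    for k, cls in enumerate(classes)
                ):
                    count += 1
    return count


def _clean_instance(
    motif_patterns: tuple[str, ...],
    pattern: str,
    rng: np.random.Generator,
    alphabet: str,
    registry: MotifRegistry,
    tries: int = 60,
) -> str:
    """Instantiate a pattern, preferring wildcard fills that spawn no
    hits of other registry motifs inside the instance.

    Some collisions are structural (G[ML]G always contains a GXG match)
    and cannot be avoided; the least-colliding instance is kept then.
    """
    best = None
    best_extra = None
    for _ in range(tries):
        inst = _instantiate(pattern, rng, alphabet)
        extra = _extra_hits_within(inst, motif_patterns, registry)
        if extra == 0:
            return inst
        if best_extra is None or extra < best_extra:
            best, best_extra = inst, extra
    return best


def _scrub(
    seq: list[str],
    planted: list[tuple[int, int]],
    registry: MotifRegistry,
    rng: np.random.Generator,
    alphabet: str,
    max_rounds: int = 200,
) -> None:
    """Mutate away registry hits that fall outside the planted intervals.

    A hit is left alone when every one of its positions lies inside a
    planted interval (emergent overlaps of planted motifs are part of
    the plant); otherwise the first free position is resampled until the
    scan is clean.
    """
    compiled = {
        e.name: [parse_pattern(p) for p in e.patterns]
        for e in registry
        if e.kind == "pattern"
    }

    def matching_classes(name: str, matched: str):
        """Per-variant class tuples that currently match the substring."""
        out = []
        for classes in compiled[name]:
            if len(classes) != len(matched):
                continue
            if all(cl is None or c in cl for c, cl in zip(matched, classes)):
                out.append(classes)
        return out

    for _ in range(max_rounds):
        dirty = False
        residues = "".join(seq)
        for name, hits in scan_registry(registry, residues).items():
            for h in hits:
                free = [p for p in range(h.start, h.end + 1)
                        if not _in_intervals(p, planted)]
                if not free:
                    continue  # emergent overlap of planted motifs: keep
                variants = matching_classes(name, h.matched)
                for pos in free:
                    off = pos - h.start
                    specific = {
                        letter
                        for classes in variants
                        if classes[off] is not None
                        for letter in classes[off]
                    }
                    if not specific:
                        continue  # wildcard for every variant: cannot break here
                    choices = [
                        c for c in alphabet
                        if c not in specific and c != seq[pos - 1]
                    ]
                    if not choices:
                        continue
                    seq[pos - 1] = choices[int(rng.integers(0, len(choices)))]
                    dirty = True
                    break
        if not dirty:
            return
    raise RuntimeError("motif scrubbing did not converge")


# --- template construction -------------------------------------------------

_NO_C = CANONICAL.replace("C", "")
_TAIL_SAFE = _NO_C  # alphabet for most planted-background positions
_PAIR_ZONE_SAFE = "".join(c for c in _NO_C if c not in "RE")


def _jittered_anchors(rng: np.random.Generator) -> dict:
    """Anchor positions with ±10 jitter, resampled until well-ordered."""
    for _ in range(1000):
        a = {
            k: v + int(rng.integers(-ANCHOR_JITTER, ANCHOR_JITTER + 1))
            for k, v in TEMPLATE_ANCHORS.items()
        }
        if (
            a["PCP"] >= 5
            and a["PCP"] + 2 < a["S[IL]G"] - 1
            and a["S[IL]G"] + 2 < a["distal"] - 1
            and a["distal"] + 2 < a["SXXRXD"] - 1
            and a["SXXRXD"] + 5 < a["R"] - 1
        ):
            return a
    raise RuntimeError("anchor jitter failed to produce a valid layout")


def _build_upo_template(
    rng: np.random.Generator,
    registry: MotifRegistry,
    subfamily: str | None,
    distal: str = "EGD",
    spacing: int = TEMPLATE_SPACING,
) -> tuple[list[str], list[tuple[int, int]], dict]:
    """A grammar-complete UPO sequence, optionally with subfamily plants.

    Returns (residue list, planted intervals, coords dict).
    """
    anchors = _jittered_anchors(rng)
    length = TEMPLATE_LENGTH
    e_pos = anchors["R"] + spacing + 1
    seq = _sample_letters(rng, length, _NO_C)
    # keep everything downstream of SXXRXD free of stray R/E in the
    # background, so the planted stabilizer/glutamate is the only
    # candidate acid-base pair
    for p in range(anchors["SXXRXD"] + 6, length + 1):
        seq[p - 1] = _PAIR_ZONE_SAFE[rng.integers(0, len(_PAIR_ZONE_SAFE))]

    planted: list[tuple[int, int]] = []
    coords: dict[str, tuple[int, int]] = {}

    def put(name: str, pos: int, text: str) -> None:
        for i, c in enumerate(text):
            seq[pos - 1 + i] = c
        planted.append((pos, pos + len(text) - 1))
        coords[name] = (pos, pos + len(text) - 1)

    put("PCP", anchors["PCP"], "PCP")
    put("S[IL]G", anchors["S[IL]G"], "SIG")
    put("distal", anchors["distal"], distal)
    put("SXXRXD", anchors["SXXRXD"],
        _clean_instance(registry["SXXRXD"].patterns, "SXXRXD", rng,
                        _PAIR_ZONE_SAFE, registry))
    put("R", anchors["R"], "R")
    put("E", e_pos, "E")

    if subfamily is not None:
        _plant_subfamily_block(seq, planted, coords, subfamily, rng, registry)

    _scrub(seq, planted, registry, rng, _NO_C)
    return seq, planted, coords


def _plant_subfamily_block(
    seq: list[str],
    planted: list[tuple[int, int]],
    coords: dict,
    subfamily: str,
    rng: np.random.Generator,
    registry: MotifRegistry,
) -> None:
    """Write a subfamily's signature motifs into the tail after the Glu."""
    length = len(seq)
    e_pos = coords["E"][0]
    cursor = e_pos + 3 + int(rng.integers(0, 3))

    def put(name: str, pos: int, text: str) -> None:
        for i, c in enumerate(text):
            seq[pos - 1 + i] = c
        planted.append((pos, pos + len(text) - 1))
        coords[name] = (pos, pos + len(text) - 1)

    for name, pattern in SUBFAMILY_PLANTS[subfamily]:
        inst = _clean_instance(registry[name].patterns, pattern, rng,
                               _PAIR_ZONE_SAFE, registry)
        if cursor + len(inst) - 1 > length:
            raise ValueError("template too short to host the signature block")
        put(name, cursor, inst)
        cursor += len(inst) + 2 + int(rng.integers(0, 3))
    if subfamily == "I":  # disulfide evidence: two Cys outside PCP
        for off in (0, 4):
            pos = cursor + off
            if pos > length:
                raise ValueError("template too short for Cys pair")
            put(f"C{off}", pos, "C")


def _derive_subfamily_template(
    master: tuple[list[str], list[tuple[int, int]], dict],
    subfamily: str,
    divergence: float,
    rng: np.random.Generator,
    registry: MotifRegistry,
) -> tuple[list[str], list[tuple[int, int]], dict]:
    """A subfamily founder: master core + signature block + divergence."""
    m_seq, m_planted, m_coords = master
    seq = list(m_seq)
    planted = list(m_planted)
    coords = dict(m_coords)
    _plant_subfamily_block(seq, planted, coords, subfamily, rng, registry)
    _mutate_in_place(seq, divergence, planted, rng)
    _limit_stray_cys(seq, planted, rng)
    _scrub(seq, planted, registry, rng, _NO_C)
    return seq, planted, coords


def _derive_cpo_template(
    master: tuple[list[str], list[tuple[int, int]], dict],
    divergence: float,
    rng: np.random.Generator,
    registry: MotifRegistry,
) -> tuple[list[str], list[tuple[int, int]], dict]:
    """A distant CPO-grammar homolog of the master: PCP < EHD < Glu.

    The master's EGD distal motif is replaced by EHD in place; the
    S[IL]G / SXXRXD motifs and the stabilizer are no longer planted and
    are scrubbed away, so the UPO grammar cannot complete.
    """
    m_seq, m_planted, m_coords = master
    seq = list(m_seq)
    ds, de = m_coords["distal"]
    for i, c in enumerate("EHD"):
        seq[ds - 1 + i] = c
    planted = [m_coords["PCP"], (ds, de), m_coords["E"]]
    coords = {"PCP": m_coords["PCP"], "distal": (ds, de), "E": m_coords["E"]}
    _mutate_in_place(seq, divergence, planted, rng)
    _scrub(seq, planted, registry, rng, _NO_C)
    return seq, planted, coords


def _limit_stray_cys(
    seq: list[str],
    planted: list[tuple[int, int]],
    rng: np.random.Generator,
    keep: int = 0,
) -> None:
    """Cap cysteines outside the planted intervals.

    Keeps the disulfide evidence rule (two Cys outside PCP) an exclusive
    property of the sequences it was planted into; the cap must be zero
    strays because some signature motifs (CDA) already plant one Cys.
    """
    positions = [
        i + 1 for i, c in enumerate(seq)
        if c == "C" and not _in_intervals(i + 1, planted)
    ]
    for p in positions[keep:]:
        seq[p - 1] = _NO_C[int(rng.integers(0, len(_NO_C)))]


def _mutate_in_place(
    seq: list[str],
    rate: float,
    planted: list[tuple[int, int]],
    rng: np.random.Generator,
) -> None:
    mask = _mutation_mask(rng, len(seq), rate)
    for i, hit in enumerate(mask):
        if not hit or _in_intervals(i + 1, planted):
            continue
        choices = CANONICAL.replace(seq[i], "")
        seq[i] = choices[int(rng.integers(0, len(choices)))]


def mutate_variant(
    seq: ProteinRecord,
    rate: float,
    seed: int | np.random.Generator,
    preserve_motifs: bool = True,
    motif_intervals: list[tuple[int, int]] | None = None,
) -> ProteinRecord:
    """Per-position substitution cloud around a parent sequence.

    Each position substitutes to one of the other 19 canonical letters
    with probability ``rate``; with ``preserve_motifs`` positions inside
    ``motif_intervals`` (1-based inclusive) are exempt.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate outside [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    intervals = motif_intervals or []
    chars = list(seq.residues)
    mask = _mutation_mask(rng, len(chars), rate)
    for i, hit in enumerate(mask):
        if not hit:
            continue
        if preserve_motifs and _in_intervals(i + 1, intervals):
            continue
        choices = CANONICAL.replace(chars[i], "")
        chars[i] = choices[rng.integers(0, len(choices))]
    return ProteinRecord(
        id=seq.id, residues="".join(chars), description=seq.description,
        source="synthetic",
    )


def _coords_str(coords: dict) -> str:
    return ";".join(f"{k}:{s}-{e}" for k, (s, e) in coords.items())


def generate_proteome(
    spec: SyntheticSpec, registry: MotifRegistry | None = None
) -> SyntheticProteome:
    """Generate a proteome with planted targets, decoys, and ground truth.

    Every planted UPO verifies its intended grammar class and subfamily
    plant before emission; decoys are resampled until they carry no
    complete core grammar.  The returned truth table maps every emitted
    id to its intended label exactly once.
    """
    registry = registry if registry is not None else default_registry()
    rng = np.random.default_rng(spec.seed)

    # master: plain UPO-core anatomy without subfamily signatures; doubles
    # as the query, and every planted family descends from it so that the
    # homology screen sees genuine relatives
    master = _build_upo_template(rng, registry, None)
    query = ProteinRecord("query_upo", "".join(master[0]),
                          "synthetic AaeUPO-like query", "synthetic")

    records: list[ProteinRecord] = []
    rows: list[dict] = []

    def check_grammar(rec: ProteinRecord, intended: str) -> None:
        got = find_core_grammar(rec, registry).grammar_class
        if got != intended:
            raise RuntimeError(
                f"planted {rec.id} scored {got!r}, intended {intended!r}"
            )

    for fam, count in spec.subfamily_counts:
        if count == 0:
            continue
        t_seq, t_planted, t_coords = _derive_subfamily_template(
            master, fam, spec.template_divergence, rng, registry
        )
        base = ProteinRecord(f"tpl_{fam}", "".join(t_seq), source="synthetic")
        for k in range(count):
            member = mutate_variant(base, spec.mutation_rate, rng, True, t_planted)
            chars = list(member.residues)
            _limit_stray_cys(chars, t_planted, rng)
            _scrub(chars, t_planted, registry, rng, _NO_C)
            member = ProteinRecord(
                f"upo_{fam}_{k}", "".join(chars), f"planted subfamily {fam}",
                "synthetic",
            )
            check_grammar(member, "UPO_core")
            records.append(member)
            rows.append(
                {"id": member.id, "grammar_class": "UPO_core", "family": fam,
                 "coords": _coords_str(t_coords)}
            )

    # CPO-grammar plants clustered around two anchors by mutation budget
    pog_seq, pog_planted, pog_coords = _derive_cpo_template(
        master, spec.cpo_divergence, rng, registry
    )
    cpo_seq, cpo_planted, cpo_coords = _derive_cpo_template(
        master, spec.cpo_divergence, rng, registry
    )
    anchors = {"anchor_pog": "pog", "anchor_cpo": "classic_cpo"}
    anchor_records = [
        ProteinRecord("anchor_pog", "".join(pog_seq), "MroUPO-like Pog anchor",
                      "synthetic"),
        ProteinRecord("anchor_cpo", "".join(cpo_seq), "classic CPO anchor",
                      "synthetic"),
    ]
    budget_rate = spec.cpo_mutation_budget / TEMPLATE_LENGTH
    for label, parent, planted, coords, count in (
        ("Pog", anchor_records[0], pog_planted, pog_coords, spec.pog_like),
        ("classic_CPO", anchor_records[1], cpo_planted, cpo_coords,
         spec.classic_like),
    ):
        for k in range(count):
            member = mutate_variant(parent, budget_rate, rng, True, planted)
            chars = list(member.residues)
            _scrub(chars, planted, registry, rng, _NO_C)
            member = ProteinRecord(
                f"cpo_{label}_{k}".lower(), "".join(chars),
                f"planted CPO-grammar ({label}-derived)", "synthetic",
            )
            check_grammar(member, "CPO_core")
            records.append(member)
            rows.append(
                {"id": member.id, "grammar_class": "CPO_core", "family": label,
                 "coords": _coords_str(coords)}
            )

    # decoys: background-only, verified grammar-free
    lo, hi = spec.decoy_length
    bg = spec.background
    for k in range(spec.decoys):
        while True:
            n = int(rng.integers(lo, hi + 1))
            if bg is None:
                residues = "".join(_sample_letters(rng, n, CANONICAL))
            else:
                # integer sampling against a scaled cumulative distribution
                cum = np.cumsum(np.round(np.asarray(bg) * 1_000_000)).astype(int)
                draws = rng.integers(0, cum[-1], size=n)
                residues = "".join(
                    CANONICAL[int(np.searchsorted(cum, d, side="right"))]
                    for d in draws
                )
            rec = ProteinRecord(f"decoy_{k}", residues, "background decoy",
                                "synthetic")
            if find_core_grammar(rec, registry).grammar_class == "none":
                break
        records.append(rec)
        rows.append({"id": rec.id, "grammar_class": "none", "family": "decoy",
                     "coords": ""})

    truth = pd.DataFrame(rows, columns=["id", "grammar_class", "family", "coords"])
    if truth["id"].duplicated().any():
        raise RuntimeError("duplicate ids in truth table")
    return SyntheticProteome(
        records=records,
        query=query,
        anchors=anchors,
        anchor_records=anchor_records,
        truth=truth,
        seed=spec.seed,
    )


def write_truth_table(proteome: SyntheticProteome, path) -> None:
    """Emit the ground-truth table as TSV."""
    proteome.truth.to_csv(path, sep="\t", index=False)
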