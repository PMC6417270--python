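"""Core UPO/CPO motif-grammar verdicts.

The catalytic anatomy of an unspecific peroxygenase reads, from the
N-terminus: the PCP motif whose central cysteine is the proximal heme
ligand, the S[IL]G motif, the distal EGD tripeptide, the SXXRXD motif,
and finally the Arg–Glu acid-base catalyst pair with exactly six
residues between arginine and glutamate (Arg189/Glu196 in AaeUPO).
Chloroperoxidases replace EGD with EHD and use a His–Glu pair, so the
CPO grammar only requires PCP, EHD, and a downstream glutamate.  A
handful of sequences annotated as CPOs carry the UPO-style acid-base
pair but an EAD/ETD distal variant and/or a seven-residue spacing;
these receive the intermediate ``UPO_like_CPO`` verdict.

Grammar classes
---------------
``UPO_core``
    PCP < S[IL]G < EGD < SXXRXD < R < E with spacing 6.
``UPO_like_CPO``
    Same chain with distal EGD/EAD/ETD and spacing 6 or 7 (the
    canonical EGD + spacing-6 combination is claimed by ``UPO_core``
    first).
``CPO_core``
    PCP < EHD < E; no stabilizer position is defined.
``none``
    No grammar completes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from upomine.io_formats import ProteinRecord
from upomine.motifs import MotifHit, MotifRegistry, default_registry, scan_motif

#: Distal tripeptide variants accepted by each grammar class.
UPO_DISTAL = ("EGD",)
UPO_LIKE_DISTAL = ("EGD", "EAD", "ETD")
CPO_DISTAL = ("EHD",)


def pair_spacing(stabilizer_pos: int, glutamate_pos: int) -> int:
    """Residues strictly between the acid-base pair (1-based positions).

    ``pair_spacing(189, 196) == 6`` — the universal UPO spacing.
    """
    if glutamate_pos <= stabilizer_pos:
        raise ValueError(
            f"glutamate position ({glutamate_pos}) must lie downstream of the "
            f"stabilizer ({stabilizer_pos})"
        )
    return glutamate_pos - stabilizer_pos - 1


@dataclass(frozen=True)
class GrammarResult:
    """The core-grammar verdict for one sequence.

    All positions are 1-based inclusive.  ``proximal_cys`` is the middle
    residue of the matched PCP motif.  ``stabilizer_pos`` is undefined
    (``None``) for ``CPO_core``.  ``supporting`` maps motif names
    (S[IL]G, SXXRXD, NHG family) to their hits.
    """

    grammar_class: str  # UPO_core | CPO_core | UPO_like_CPO | none
    proximal_cys: int | None = None
    distal_variant: str | None = None  # EGD | EHD | EAD | ETD
    distal_pos: int | None = None
    stabilizer_pos: int | None = None
    catalytic_glu_pos: int | None = None
    spacing: int | None = None
    supporting: dict = field(default_factory=dict)

    @property
    def is_upo(self) -> bool:
        return self.grammar_class in ("UPO_core", "UPO_like_CPO")

    @property
    def is_cpo(self) -> bool:
        return self.grammar_class == "CPO_core"


def _first_pair(
    residues: str, begin: int, spacings: tuple[int, ...], stabilizer: str = "R"
) -> tuple[int, int] | None:
    """Left-most (stabilizer, glutamate) pair with an allowed spacing.

    ``begin`` is the first 1-based position considered for the
    stabilizer.  Pairs are ordered by stabilizer position, then by
    glutamate position, and the first one satisfying the spacing
    constraint wins — deterministic, and consistent with the single
    printed exemplar (Arg189/Glu196).
    """
    n = len(residues)
    for i in range(begin, n + 1):
        if residues[i - 1] != stabilizer:
            continue
        for sp in sorted(spacings):
            j = i + sp + 1
            if j <= n and residues[j - 1] == "E":
                return i, j
    return None


def find_core_grammar(
    seq: ProteinRecord,
    registry: MotifRegistry | None = None,
    *,
    require_silg: bool = True,
    require_sxxrxd: bool = True,
    min_length: int = 60,
) -> GrammarResult:
    """Classify one sequence against the core UPO/CPO grammar.

    The UPO grammar is tried first (canonical spacing 6, EGD distal),
    then the UPO-like-CPO variant grammar (EGD/EAD/ETD, spacing 6 or 7),
    then the CPO grammar; degenerate inputs yield class ``none``.

    ``require_silg`` and ``require_sxxrxd`` control whether the two
    all-UPO supporting motifs are mandatory for the UPO grammars (the
    SXXRXD motif is genuinely absent in MroUPO, hence the flags).
    """
    registry = registry if registry is not None else default_registry()
    if len(seq) < min_length:
        return GrammarResult("none")

    res = seq.residues
    pcp_hits = scan_motif(registry["PCP"], res)
    if not pcp_hits:
        return GrammarResult("none")
    silg_hits = scan_motif(registry["S[IL]G"], res) if "S[IL]G" in registry else []
    sxxrxd_hits = scan_motif(registry["SXXRXD"], res) if "SXXRXD" in registry else []
    nhg_hits = scan_motif(registry["NHG_family"], res) if "NHG_family" in registry else []
    distal_hits = {
        v: scan_motif(registry[v], res) for v in set(UPO_LIKE_DISTAL + CPO_DISTAL)
        if v in registry
    }

    def support(pcp=None, silg=None, sxxrxd=None):
        sup: dict[str, list[MotifHit]] = {}
        if silg is not None:
            sup["S[IL]G"] = [silg]
        elif silg_hits:
            sup["S[IL]G"] = list(silg_hits)
        if sxxrxd is not None:
            sup["SXXRXD"] = [sxxrxd]
        elif sxxrxd_hits:
            sup["SXXRXD"] = list(sxxrxd_hits)
        if nhg_hits:
            sup["NHG_family"] = list(nhg_hits)
        return sup

    def try_upo(variants: tuple[str, ...], spacings: tuple[int, ...], cls: str):
        # Ordered chain search, earliest completion wins.  Each element
        # must start strictly after the previous element ends.
        for pcp in pcp_hits:
            silg_opts = (
                [h for h in silg_hits if h.start > pcp.end]
                if require_silg
                else [None]
            )
            if require_silg and not silg_opts:
                continue
            for silg in silg_opts:
                after_silg = silg.end if silg else pcp.end
                for variant in variants:
                    for dh in distal_hits.get(variant, []):
                        if dh.start <= after_silg:
                            continue
                        sx_opts = (
                            [h for h in sxxrxd_hits if h.start > dh.end]
                            if require_sxxrxd
                            else [None]
                        )
                        if require_sxxrxd and not sx_opts:
                            continue
                        for sx in sx_opts:
                            begin = (sx.end if sx else dh.end) + 1
                            pair = _first_pair(res, begin, spacings)
                            if pair is None:
                                continue
                            r_pos, e_pos = pair
                            return GrammarResult(
                                cls,
                                proximal_cys=pcp.start + 1,
                                distal_variant=variant,
                                distal_pos=dh.start,
                                stabilizer_pos=r_pos,
                                catalytic_glu_pos=e_pos,
                                spacing=pair_spacing(r_pos, e_pos),
                                supporting=support(pcp, silg, sx),
                            )
        return None

    result = try_upo(UPO_DISTAL, (6,), "UPO_core")
    if result is not None:
        return result
    result = try_upo(UPO_LIKE_DISTAL, (6, 7), "UPO_like_CPO")
    if result is not None:
        return result

    # CPO grammar: PCP < EHD < downstream E (no stabilizer).
    for pcp in pcp_hits:
        for dh in distal_hits.get("EHD", []):
            if dh.start <= pcp.end:
                continue
            e_pos = res.find("E", dh.end)  # 0-based index dh.end == first pos after hit
            if e_pos >= 0:
                return GrammarResult(
                    "CPO_core",
                    proximal_cys=pcp.start + 1,
                    distal_variant="EHD",
                    distal_pos=dh.start,
                    stabilizer_pos=None,
                    catalytic_glu_pos=e_pos + 1,
                    spacing=None,
                    supporting=support(pcp),
                )
    return GrammarResult("none")


def aromatic_context(
    seq: ProteinRecord, grammar: GrammarResult, window: int = 15
) -> int:
    """Count aromatic residues (F/Y/W) around the distal motif.

    A sequence-level descriptor of the aromatic lining of the substrate
    channel (the binding pocket of AaeUPO is surrounded by aromatic side
    chains).  Purely a reported annotation: it is *not* a structural
    check and never filters candidates.
    """
    if grammar.grammar_class == "none" or grammar.distal_pos is None:
        raise ValueError("aromatic_context requires a sequence with a grammar verdict")
    mid = grammar.distal_pos + 1  # middle of the distal tripeptide
    lo = max(1, mid - window)
    hi = min(len(seq), mid + window)
    return sum(1 for c in seq.residues[lo - 1 : hi] if c in "FYW")
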