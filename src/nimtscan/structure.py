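"""Cloverleaf-structure-aware comparison of tRNA-lookalikes to references.

A tRNA cloverleaf is modeled as a dot-bracket secondary structure over the
gene sequence (DNA alphabet; T stands in for U).  The four arms are
recovered from the branching pattern: the helix closing the molecule from
the 5'/3' ends is the acceptor stem, and the helices branching off the
central multiloop are, in 5'->3' order, the D-arm, the anticodon arm and
the T-arm.  Mitochondrial tRNAs may lack an arm entirely (the D-armless
serine isoacceptor); a structure with one inner helix missing is parsed
with an empty D-arm, which is the configuration known from mitochondrial
tRNAs.

Substitutions relative to the reference are classified by their
structural consequence: changes at unpaired positions (``loop``), paired
positions that retain Watson-Crick pairing (``compensatory``), pairs
shifted to a G-U wobble (``wobble_shift``), pairs broken outright
(``disruptive``), and gap columns (``deletion``/``insertion``).
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import global_align_columns
from .core import SequenceRecord, revcomp

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}

ARM_NAMES = ("acceptor", "D", "anticodon", "T")


@dataclass(frozen=True)
class CloverleafModel:
    """A tRNA sequence with its cloverleaf secondary structure.

    ``pair_table`` maps each paired position to its partner (symmetric);
    ``arms`` maps arm name -> frozenset of positions.  The acceptor arm
    holds only the paired stem positions; inner arms span their full
    stem-loop region.
    """

    sequence: str
    structure: str
    pair_table: dict[int, int]
    arms: dict[str, frozenset[int]]

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs as (i, j) with i < j, sorted by i."""
        return sorted((i, j) for i, j in self.pair_table.items() if i < j)

    def __len__(self) -> int:
        return len(self.sequence)


def _pair_table(dot_bracket: str) -> dict[int, int]:
    table: dict[int, int] = {}
    stack: list[int] = []
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            table[i] = j
            table[j] = i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return table


def parse_cloverleaf(sequence: str, dot_bracket: str) -> CloverleafModel:
    """Build a CloverleafModel, segmenting arms from the branching pattern.

    Raises ``ValueError`` for unbalanced brackets, length mismatch, or a
    branching pattern with more than three inner helices (not a
    cloverleaf).
    """
    seq = SequenceRecord("x", sequence).sequence
    if len(seq) != len(dot_bracket):
        raise ValueError("sequence and structure lengths differ")
    table = _pair_table(dot_bracket)

    # Walk the acceptor helix: outermost pairs, following chains of
    # single-branch pairs (absorbing bulges) until the multiloop.
    def branch_children(i: int, j: int) -> list[tuple[int, int]]:
        """Outermost pairs strictly inside (i, j), in 5'->3' order."""
        out = []
        k = i + 1
        while k < j:
            if k in table and table[k] > k:
                out.append((k, table[k]))
                k = table[k] + 1
            else:
                k += 1
        return out

    top = branch_children(-1, len(seq))
    acceptor: set[int] = set()
    if len(top) == 1:
        i, j = top[0]
        children = branch_children(i, j)
        while len(children) == 1:
            acceptor.update((i, j))
            (i, j) = children[0]
            children = branch_children(i, j)
        if children:  # (i, j) closes the multiloop
            acceptor.update((i, j))
            inner = children
        else:  # hairpin only: a single helix, no multiloop
            acceptor.update((i, j))
            inner = []
    else:
        # No single closing helix: the top level itself is the multiloop.
        inner = top

    if len(inner) > 3:
        raise ValueError(f"{len(inner)} inner helices: not a cloverleaf")
    spans = [frozenset(range(i, j + 1)) for i, j in inner]
    arms: dict[str, frozenset[int]] = {
        "acceptor": frozenset(acceptor),
        "D": frozenset(), "anticodon": frozenset(), "T": frozenset(),
    }
    if len(spans) == 3:
        arms["D"], arms["anticodon"], arms["T"] = spans
    elif len(spans) == 2:
        # Three-helix structures are taken as D-armless, the configuration
        # known from the mitochondrial serine isoacceptor.
        arms["anticodon"], arms["T"] = spans
    elif len(spans) == 1:
        arms["anticodon"] = spans[0]
    return CloverleafModel(seq, dot_bracket, table, arms)


@dataclass(frozen=True)
class SubstitutionClass:
    """Classification of one differing/gap alignment column."""

    position: int  # reference column; -1 for insertions
    kind: str      # loop | compensatory | wobble_shift | disruptive | deletion | insertion
    ref_base: str = ""
    cand_base: str = ""


@dataclass
class ChangeSummary:
    counts: dict[str, int]
    n_ref_pairs: int
    n_preserved_pairs: int

    @property
    def structure_score(self) -> float:
        """Fraction of reference pairs preserved (WC or wobble) in the candidate."""
        if self.n_ref_pairs == 0:
            return 1.0
        return self.n_preserved_pairs / self.n_ref_pairs


def _can_pair(a: str, b: str) -> str | None:
    if (a, b) in WC_PAIRS:
        return "WC"
    if (a, b) in WOBBLE_PAIRS:
        return "GU"
    return None


def classify_changes(
    ref: CloverleafModel,
    candidate: SequenceRecord | str,
    alignment: list[tuple[int | None, int | None]] | None = None,
) -> tuple[list[SubstitutionClass], ChangeSummary]:
    """Classify every differing column of candidate vs reference.

    ``alignment`` is a list of (ref_col, cand_col) pairs with ``None``
    marking gaps; when omitted it is computed with the unit-cost global
    aligner.  Returns the per-column classes and a summary whose
    structure-conservation score is the fraction of reference base pairs
    still formed (Watson-Crick or G-U) by the aligned candidate bases.
    """
    cand = candidate.sequence if isinstance(candidate, SequenceRecord) else \
        SequenceRecord("cand", candidate).sequence
    if alignment is None:
        alignment = global_align_columns(ref.sequence, cand)
    ref_to_cand: dict[int, int | None] = {}
    for rc, cc in alignment:
        if rc is not None:
            if rc >= len(ref.sequence) or (cc is not None and cc >= len(cand)):
                raise ValueError("alignment columns out of range")
            ref_to_cand[rc] = cc
        elif cc is not None and cc >= len(cand):
            raise ValueError("alignment columns out of range")

    classes: list[SubstitutionClass] = []
    for rc, cc in alignment:
        if rc is None:
            classes.append(SubstitutionClass(-1, "insertion", "", cand[cc]))
            continue
        rb = ref.sequence[rc]
        if cc is None:
            classes.append(SubstitutionClass(rc, "deletion", rb, ""))
            continue
        cb = cand[cc]
        if cb == rb:
            continue
        partner = ref.pair_table.get(rc)
        if partner is None:
            classes.append(SubstitutionClass(rc, "loop", rb, cb))
            continue
        pc = ref_to_cand.get(partner)
        if pc is None:
            classes.append(SubstitutionClass(rc, "disruptive", rb, cb))
            continue
        a, b = (cb, cand[pc]) if rc < partner else (cand[pc], cb)
        kind = _can_pair(a, b)
        if kind == "WC":
            classes.append(SubstitutionClass(rc, "compensatory", rb, cb))
        elif kind == "GU":
            # A wobble-shifted pair still pairs, but asymmetrically; this
            # is distinct from a compensatory WC replacement whether the
            # reference pair was WC or already wobble.
            classes.append(SubstitutionClass(rc, "wobble_shift", rb, cb))
        else:
            classes.append(SubstitutionClass(rc, "disruptive", rb, cb))

    n_pairs = 0
    n_preserved = 0
    for i, j in ref.pairs:
        n_pairs += 1
        ci, cj = ref_to_cand.get(i), ref_to_cand.get(j)
        if ci is None or cj is None:
            continue
        if _can_pair(cand[ci], cand[cj]) is not None:
            n_preserved += 1
    counts: dict[str, int] = {k: 0 for k in
                              ("loop", "compensatory", "wobble_shift",
                               "disruptive", "deletion", "insertion")}
    for c in classes:
        counts[c.kind] += 1
    return classes, ChangeSummary(counts, n_pairs, n_preserved)


def detect_arm_deletion(
    ref: CloverleafModel,
    alignment: list[tuple[int | None, int | None]],
    min_fraction: float = 0.6,
) -> set[str]:
    """Arms whose reference positions are mostly aligned to gaps.

    An arm is reported deleted iff at least ``min_fraction`` of its
    reference positions align to gap columns.
    """
    gapped = {rc for rc, cc in alignment if rc is not None and cc is None}
    deleted = set()
    for name in ARM_NAMES:
        positions = ref.arms.get(name, frozenset())
        if not positions:
            continue
        frac = len(positions & gapped) / len(positions)
        if frac >= min_fraction:
            deleted.add(name)
    return deleted


def reverse_complement_structure(model: CloverleafModel) -> tuple[CloverleafModel, int]:
    """Reverse-complement a model; count base pairs that no longer form.

    Watson-Crick pairs survive reverse complementation (they are
    self-complementary as pairs), whereas a G-U wobble maps to A-C, which
    cannot pair.  Lost pairs are dropped from the returned model's
    structure; the count of lost pairs is returned alongside.
    """
    L = len(model.sequence)
    new_seq = revcomp(model.sequence)
    lost = 0
    kept_pairs = []
    for i, j in model.pairs:
        ni, nj = L - 1 - j, L - 1 - i
        if _can_pair(new_seq[ni], new_seq[nj]) is not None:
            kept_pairs.append((ni, nj))
        else:
            lost += 1
    db = ["."] * L
    for i, j in kept_pairs:
        db[i], db[j] = "(", ")"
    new_model = parse_cloverleaf(new_seq, "".join(db))
    return new_model, lost
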