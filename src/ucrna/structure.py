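"""RNA secondary structure: dot-bracket parsing, loop decomposition and a
baseline maximum-pairing (Nussinov) folder.

A structure is a sequence plus a dot-bracket string of equal length in
which matched parentheses are base pairs (Watson-Crick or GU wobble)
and dots are unpaired.  The loop decomposition partitions every
position into exactly one element: a helix (paired) or one loop
element (hairpin, bulge, internal, multibranch or exterior).
"""

from __future__ import annotations

from dataclasses import dataclass

CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)

LOOP_TYPES = ("hairpin", "internal", "bulge", "multibranch", "exterior")


def can_pair(x: str, y: str) -> bool:
    return (x, y) in CANONICAL_PAIRS


@dataclass
class RnaStructure:
    """A folded RNA: sequence + dot-bracket, validated on construction."""

    seq_id: str
    sequence: str
    dotbracket: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError(
                f"{self.seq_id}: sequence and structure lengths differ "
                f"({len(self.sequence)} vs {len(self.dotbracket)})"
            )
        bad = set(self.sequence) - set("ACGUN")
        if bad:
            raise ValueError(f"{self.seq_id}: non-RNA characters {sorted(bad)}")
        self.pair_table  # validates brackets and pair chemistry

    @property
    def pair_table(self) -> list[int]:
        """0-based partner index per position, -1 if unpaired."""
        pt = [-1] * len(self.dotbracket)
        stack: list[int] = []
        for i, ch in enumerate(self.dotbracket):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"{self.seq_id}: unbalanced ')' at position {i + 1}")
                j = stack.pop()
                if not can_pair(self.sequence[j], self.sequence[i]):
                    raise ValueError(
                        f"{self.seq_id}: non-canonical pair "
                        f"{self.sequence[j]}{self.sequence[i]} at {j + 1},{i + 1}"
                    )
                pt[j], pt[i] = i, j
            elif ch != ".":
                raise ValueError(f"{self.seq_id}: invalid character {ch!r} in structure")
        if stack:
            raise ValueError(f"{self.seq_id}: unbalanced '(' at position {stack[-1] + 1}")
        return pt

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LoopElement:
    """One loop of a structure's decomposition.

    ``positions`` are 1-based and unpaired in the parent; contiguous for
    hairpin/bulge/exterior, possibly two or more runs for internal and
    multibranch loops.
    """

    parent_id: str
    loop_type: str
    positions: list[int]
    subsequence: str

    def __len__(self) -> int:
        return len(self.positions)


def _children(pt: list[int], i: int, j: int) -> list[tuple[int, int]]:
    """Maximal base pairs immediately interior to interval (i, j) exclusive."""
    kids = []
    k = i + 1
    while k < j:
        if pt[k] > k:
            kids.append((k, pt[k]))
            k = pt[k] + 1
        else:
            k += 1
    return kids


def extract_loops(
    s: RnaStructure,
    min_loop_len: int = 1,
    types: set[str] | None = None,
) -> list[LoopElement]:
    """Decompose a structure into its loop elements.

    A hairpin loop is the maximal unpaired run enclosed by a closing
    pair with no inner pairs; bulges and internal loops are the unpaired
    runs between two consecutive helices (one-sided / two-sided);
    multibranch loops collect all unpaired runs of a junction with >=2
    enclosed helices; exterior elements are unpaired runs outside all
    pairs.  Only elements of the requested ``types`` with at least
    ``min_loop_len`` positions are returned, ordered by first position.
    """
    if types is None:
        types = set(LOOP_TYPES)
    unknown = types - set(LOOP_TYPES)
    if unknown:
        raise ValueError(f"unknown loop types: {sorted(unknown)}")
    pt = s.pair_table
    n = len(s)
    elements: list[LoopElement] = []

    def add(loop_type: str, positions: list[int]) -> None:
        if positions:
            elements.append(
                LoopElement(
                    parent_id=s.seq_id,
                    loop_type=loop_type,
                    positions=[p + 1 for p in positions],
                    subsequence="".join(s.sequence[p] for p in positions),
                )
            )

    # exterior runs (virtual enclosing interval [-1, n])
    run: list[int] = []
    k = 0
    while k < n:
        if pt[k] == -1:
            run.append(k)
            k += 1
        else:
            add("exterior", run)
            run = []
            k = pt[k] + 1
    add("exterior", run)

    for i in range(n):
        j = pt[i]
        if j <= i:
            continue  # not an opening pair
        kids = _children(pt, i, j)
        # unpaired positions at the top level of (i, j), outside children
        inner = []
        k = i + 1
        while k < j:
            if pt[k] == -1:
                inner.append(k)
                k += 1
            else:
                k = pt[k] + 1
        if not kids:
            add("hairpin", inner)
        elif len(kids) == 1:
            (p, q) = kids[0]
            left = list(range(i + 1, p))
            right = list(range(q + 1, j))
            if left and right:
                add("internal", left + right)
            elif left or right:
                add("bulge", left or right)
            # stacked helix: no loop element
        else:
            add("multibranch", inner)

    elements.sort(key=lambda e: e.positions[0])
    return [e for e in elements if e.loop_type in types and len(e) >= min_loop_len]


def fold_baseline(seq_id: str, sequence: str, min_hairpin: int = 3) -> RnaStructure:
    """Maximum base-pairing (Nussinov) fold with hairpin loops of at
    least ``min_hairpin`` unpaired bases; GU allowed.

    The traceback is deterministic: at ties it prefers leaving the
    3'-end unpaired, and among bifurcations the pairing with the
    smallest opening index.  This is a zero-dependency baseline and is
    not claimed to reproduce minimum-free-energy structures; externally
    predicted structures can be supplied in Vienna format instead.
    """
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"{seq_id}: non-RNA characters {sorted(bad)}")
    n = len(seq)
    N = [[0] * n for _ in range(n)]
    for span in range(min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i][j - 1]  # j unpaired
            for k in range(i, j - min_hairpin):
                if can_pair(seq[k], seq[j]):
                    left = N[i][k - 1] if k > i else 0
                    cand = left + 1 + N[k + 1][j - 1]
                    if cand > best:
                        best = cand
            N[i][j] = best
    db = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_hairpin:
            continue
        if N[i][j] == N[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_hairpin):
            if can_pair(seq[k], seq[j]):
                left = N[i][k - 1] if k > i else 0
                if left + 1 + N[k + 1][j - 1] == N[i][j]:
                    db[k], db[j] = "(", ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
    return RnaStructure(seq_id, seq, "".join(db))
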