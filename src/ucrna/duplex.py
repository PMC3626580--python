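"""Minimum-free-energy intermolecular RNA duplex by dynamic programming.

The model is a kissing-interaction hybridization energy: duplex
initiation penalty, nearest-neighbor stacking terms for adjacent base
pairs, and size-dependent penalties for small interior loops/bulges
(total unpaired size capped by the bundled table, default 4).
Intramolecular pairs are forbidden; the two strands hybridize
antiparallel and pairings are non-crossing.  Parameters come from the
plain-text table bundled with the package (see ``data/nn_params.tsv``),
which is the single source of truth for both this DP and any oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .structure import LoopElement, can_pair

_PARAMS_CACHE = None


@dataclass(frozen=True)
class NnParams:
    """Nearest-neighbor parameter set (kcal/mol)."""

    init: float
    loop_penalty: dict  # total unpaired size -> penalty
    stacks: dict  # ((p1, p2), (q1, q2)) -> dG

    @property
    def max_loop(self) -> int:
        return max(self.loop_penalty)

    def stack(self, p: tuple[str, str], q: tuple[str, str]) -> float:
        try:
            return self.stacks[(p, q)]
        except KeyError:
            raise KeyError(
                f"parameter table has no stack entry for step "
                f"{''.join(p)}/{''.join(q)}"
            ) from None


def load_params(path=None) -> NnParams:
    """Load the nearest-neighbor table (bundled file by default)."""
    global _PARAMS_CACHE
    if path is None and _PARAMS_CACHE is not None:
        return _PARAMS_CACHE
    if path is None:
        text = (resources.files("ucrna") / "data" / "nn_params.tsv").read_text("utf-8")
    else:
        text = open(path, encoding="utf-8").read()
    init = None
    loops: dict[int, float] = {}
    stacks: dict = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "init":
            init = float(fields[1])
        elif fields[0] == "loop":
            loops[int(fields[1])] = float(fields[2])
        elif fields[0] == "stack":
            p = (fields[1][0], fields[1][1])
            q = (fields[2][0], fields[2][1])
            stacks[(p, q)] = float(fields[3])
        else:
            raise ValueError(f"unknown parameter record {fields[0]!r}")
    if init is None or not loops or not stacks:
        raise ValueError("incomplete nearest-neighbor parameter table")
    params = NnParams(init=init, loop_penalty=loops, stacks=stacks)
    if path is None:
        _PARAMS_CACHE = params
    return params


@dataclass
class DuplexPrediction:
    """An intermolecular duplex between two (loop) sequences.

    ``paired_positions`` are 0-based (i in a, j in b); the pairing is
    antiparallel and non-crossing.  ``bond_fraction`` is the number of
    base pairs divided by the shorter sequence length (strict ">0.75"
    screening reads on this number).
    """

    loop_a: LoopElement | None
    loop_b: LoopElement | None
    paired_positions: list[tuple[int, int]]
    delta_g: float
    bond_fraction: float


def duplex_energy(
    a: str, b: str, params: NnParams | None = None, denominator: str = "shorter"
) -> DuplexPrediction | None:
    """Minimum-energy duplex between RNA strings ``a`` and ``b``.

    Returns None (the no-duplex sentinel) when no Watson-Crick or GU
    pair exists between the two sequences.  ``denominator`` selects the
    bond-fraction reference: "shorter" (default) or "union" (both loop
    lengths combined, each pair contributing two bonded nucleotides).
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    if params is None:
        params = load_params()
    a = a.upper().replace("T", "U")
    b = b.upper().replace("T", "U")
    n, m = len(a), len(b)
    max_loop = params.max_loop

    INF = float("inf")
    # E[i][j]: best energy of a duplex whose a-3'-most pair is (i, j)
    E = [[INF] * m for _ in range(n)]
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    any_pair = False
    for i in range(n):
        for j in range(m - 1, -1, -1):
            if not can_pair(a[i], b[j]):
                continue
            any_pair = True
            best = params.init
            parent = None
            for ip in range(max(0, i - max_loop - 1), i):
                for jp in range(j + 1, min(m, j + max_loop + 2)):
                    if E[ip][jp] == INF:
                        continue
                    ga = i - ip - 1
                    gb = jp - j - 1
                    if ga == 0 and gb == 0:
                        step = params.stack((a[ip], b[jp]), (a[i], b[j]))
                    else:
                        size = ga + gb
                        if size > max_loop:
                            continue
                        step = params.loop_penalty[size]
                    cand = E[ip][jp] + step
                    if cand < best - 1e-12:
                        best = cand
                        parent = (ip, jp)
            E[i][j] = best
            back[(i, j)] = parent

    if not any_pair:
        return None

    best_end, best_e = None, INF
    for i in range(n):
        for j in range(m):
            if E[i][j] < best_e - 1e-12:
                best_e = E[i][j]
                best_end = (i, j)
    pairs: list[tuple[int, int]] = []
    node = best_end
    while node is not None:
        pairs.append(node)
        node = back[node]
    pairs.reverse()

    if denominator == "shorter":
        denom = min(n, m)
        bf = len(pairs) / denom
    elif denominator == "union":
        bf = 2 * len(pairs) / (n + m)
    else:
        raise ValueError(f"unknown bond-fraction denominator {denominator!r}")
    return DuplexPrediction(
        loop_a=None,
        loop_b=None,
        paired_positions=pairs,
        delta_g=round(best_e, 10),
        bond_fraction=bf,
    )


def full_complement_energy(a: str, params: NnParams | None = None) -> float:
    """Energy of ``a`` fully hybridized to its exact reverse complement
    (every position paired, pure stack sum).  Used by the synthetic-data
    generator to certify planted loops as stable."""
    if params is None:
        params = load_params()
    a = a.upper().replace("T", "U")
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    e = params.init
    for k in range(len(a) - 1):
        p = (a[k], comp[a[k]])
        q = (a[k + 1], comp[a[k + 1]])
        e += params.stack(p, q)
    return e
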