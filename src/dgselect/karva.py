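"""Karva (GEP) chromosome encoding, validation, and decoding.

A chromosome is a fixed-structure linear string grouping one or more genes.
Each gene has a *head* of length ``h`` that may hold function symbols or
terminals (attribute IDs), and a *tail* of length ``t = h*(n-1) + 1`` that
holds terminals only, where ``n`` is the maximum arity in the function set.
The tail rule guarantees that the breadth-first decoding of any gene closes
into a valid expression tree (the phenotype).

Functions are never evaluated numerically here: classification uses the raw
expression values of the *expressed* terminals, so function symbols act only
as arity-bearing connectors that shape which terminals a gene selects.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "FunctionSymbol",
    "FunctionSet",
    "DEFAULT_FUNCTIONS",
    "Gene",
    "Chromosome",
    "TreeNode",
    "ExpressionTree",
    "random_gene",
    "decode",
    "expressed_terminals",
    "gene_terminals",
    "validate",
    "to_karva_string",
    "from_karva_string",
]


@dataclass(frozen=True)
class FunctionSymbol:
    """A function token with its arity (number of children it takes)."""

    name: str
    arity: int

    def __post_init__(self) -> None:
        if self.arity < 1:
            raise ValueError(f"function {self.name!r} must have arity >= 1")


@dataclass(frozen=True)
class FunctionSet:
    """An immutable set of function symbols with unique names.

    ``n`` is the maximum arity, which fixes the head/tail structure rule
    ``t = h*(n-1) + 1`` for every gene built over this set.
    """

    symbols: tuple[FunctionSymbol, ...]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("function set must not be empty")
        names = [s.name for s in self.symbols]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate function names in {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.symbols)

    @property
    def n(self) -> int:
        """Maximum arity over the set."""
        return max(s.arity for s in self.symbols)

    def arity(self, token: str) -> int:
        """Arity of ``token``; 0 if it is not a function (i.e. a terminal)."""
        for s in self.symbols:
            if s.name == token:
                return s.arity
        return 0

    def __contains__(self, token: object) -> bool:
        return any(s.name == token for s in self.symbols)

    def __iter__(self) -> Iterator[FunctionSymbol]:
        return iter(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)


#: Arithmetic connectors: four binary operators plus unary square root.
DEFAULT_FUNCTIONS = FunctionSet(
    (
        FunctionSymbol("+", 2),
        FunctionSymbol("-", 2),
        FunctionSymbol("*", 2),
        FunctionSymbol("/", 2),
        FunctionSymbol("Q", 1),
    )
)


@dataclass(frozen=True)
class Gene:
    """One karva gene: ``head`` (functions or terminals) + ``tail`` (terminals)."""

    head: tuple[str, ...]
    tail: tuple[str, ...]

    @property
    def h(self) -> int:
        return len(self.head)

    @property
    def t(self) -> int:
        return len(self.tail)

    @property
    def g(self) -> int:
        """Total gene length ``h + t``."""
        return self.h + self.t

    @property
    def symbols(self) -> tuple[str, ...]:
        return self.head + self.tail


@dataclass
class Chromosome:
    """A sequence of genes sharing the same structure, plus an optional score.

    ``fitness`` is attached by the evolution loop after evaluation; it does
    not participate in equality, which compares genotypes only.
    """

    genes: tuple[Gene, ...]
    fitness: "object | None" = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("chromosome must contain at least one gene")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def length(self) -> int:
        """Chromosome length ``L = N * (h + t)``."""
        return sum(gene.g for gene in self.genes)


@dataclass(frozen=True)
class TreeNode:
    symbol: str
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class ExpressionTree:
    """Decoded phenotype of a gene.

    ``expressed_length`` is the number of leading gene positions actually
    consumed by the breadth-first fill (the K-expression length); trailing
    positions are silent.
    """

    root: TreeNode
    expressed_length: int

    def leaves(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                yield node
            else:
                stack.extend(reversed(node.children))


def random_gene(
    terminal_set: Sequence[str],
    functions: FunctionSet,
    h: int,
    rng,
) -> Gene:
    """Draw a random gene: head uniform over functions ∪ terminals, tail
    uniform over terminals.

    ``rng`` is a :class:`numpy.random.Generator`; all randomness flows
    through it so runs are reproducible.
    """
    terminals = list(terminal_set)
    if not terminals:
        raise ValueError("terminal set exhausted: cannot build a gene")
    if h < 1:
        raise ValueError(f"head length must be >= 1, got {h}")
    t = h * (functions.n - 1) + 1
    head_pool = list(functions.names) + terminals
    head = tuple(head_pool[i] for i in rng.integers(0, len(head_pool), size=h))
    tail = tuple(terminals[i] for i in rng.integers(0, len(terminals), size=t))
    return Gene(head=head, tail=tail)


def decode(gene: Gene, functions: FunctionSet = DEFAULT_FUNCTIONS) -> ExpressionTree:
    """Decode a gene into its expression tree by breadth-first (level-order)
    filling: position 0 is the root; each function node consumes the next
    ``arity`` unread positions as its ordered children; decoding stops when
    no open slots remain.
    """
    for pos, sym in enumerate(gene.tail):
        if sym in functions:
            raise ValueError(
                f"malformed gene: function {sym!r} at tail position {pos}"
            )
    symbols = gene.symbols

    # Two-phase fill: assign child slices level-order, then freeze bottom-up.
    arities = []
    consumed = 1
    queue = deque([0])
    child_index: dict[int, list[int]] = {}
    while queue:
        pos = queue.popleft()
        k = functions.arity(symbols[pos])
        arities.append(k)
        kids = list(range(consumed, consumed + k))
        child_index[pos] = kids
        consumed += k
        queue.extend(kids)

    def build(pos: int) -> TreeNode:
        return TreeNode(
            symbol=symbols[pos],
            children=tuple(build(c) for c in child_index.get(pos, ())),
        )

    return ExpressionTree(root=build(0), expressed_length=consumed)


def gene_terminals(gene: Gene, functions: FunctionSet = DEFAULT_FUNCTIONS) -> set[str]:
    """Distinct terminals appearing in the decoded expression tree of ``gene``."""
    tree = decode(gene, functions)
    return {leaf.symbol for leaf in tree.leaves()}


def expressed_terminals(
    chromosome: Chromosome, functions: FunctionSet = DEFAULT_FUNCTIONS
) -> set[str]:
    """Union of distinct terminals expressed by all genes of a chromosome.

    The cardinality of this set is the selected-attribute count ``s`` used by
    the size-penalized fitness.
    """
    out: set[str] = set()
    for gene in chromosome.genes:
        out |= gene_terminals(gene, functions)
    return out


def validate(
    chromosome: Chromosome,
    terminal_set: Iterable[str],
    functions: FunctionSet = DEFAULT_FUNCTIONS,
) -> list[str]:
    """Check all structural invariants; returns a list of violations
    (empty when the chromosome is valid). Violations are returned rather
    than raised so callers can report them in bulk.
    """
    allowed = set(terminal_set)
    violations: list[str] = []
    n = functions.n
    h0, t0 = chromosome.genes[0].h, chromosome.genes[0].t
    for gi, gene in enumerate(chromosome.genes):
        if gene.h != h0 or gene.t != t0:
            violations.append(
                f"gene {gi}: structure ({gene.h},{gene.t}) differs from gene 0 ({h0},{t0})"
            )
        if gene.t != gene.h * (n - 1) + 1:
            violations.append(
                f"gene {gi}: tail length {gene.t} != h*(n-1)+1 = {gene.h * (n - 1) + 1}"
            )
        for pos, sym in enumerate(gene.head):
            if sym not in functions and sym not in allowed:
                violations.append(
                    f"gene {gi}: head position {pos}: unknown terminal {sym!r}"
                )
        for pos, sym in enumerate(gene.tail):
            if sym in functions:
                violations.append(
                    f"gene {gi}: tail position {pos}: function {sym!r} not allowed in tail"
                )
            elif sym not in allowed:
                violations.append(
                    f"gene {gi}: tail position {pos}: unknown terminal {sym!r}"
                )
    return violations


def to_karva_string(chromosome: Chromosome) -> str:
    """Serialize to the plain-text dialect: symbols space-separated, genes
    joined by ``" | "``, e.g. ``"+ - a12 a9 a3 a11 a7 | Q a4 a1 a2 a2 a0 a5"``.
    """
    return " | ".join(" ".join(gene.symbols) for gene in chromosome.genes)


def from_karva_string(
    text: str, functions: FunctionSet = DEFAULT_FUNCTIONS
) -> Chromosome:
    """Parse the dialect written by :func:`to_karva_string`.

    The head length is inferred from the gene length via ``g = h*n + 1``
    (the only ``h`` consistent with the tail rule).
    """
    n = functions.n
    genes = []
    for part in text.split("|"):
        tokens = tuple(part.split())
        if not tokens:
            raise ValueError("empty gene in karva string")
        g = len(tokens)
        if (g - 1) % n != 0:
            raise ValueError(
                f"gene length {g} inconsistent with max arity {n} (need g = h*n+1)"
            )
        h = (g - 1) // n
        if h < 1:
            raise ValueError(f"gene length {g} too short for max arity {n}")
        genes.append(Gene(head=tokens[:h], tail=tokens[h:]))
    return Chromosome(genes=tuple(genes))
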