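"""Independent reference implementations used to cross-check the package.

These deliberately use different algorithms from the code under test (level
slicing instead of a fill queue) so structural agreement is meaningful.
"""

from dgselect.karva import FunctionSet, Gene


def decode_by_level_slices(gene: Gene, functions: FunctionSet):
    """Brute-force karva decoding: compute the size of each tree level from
    the arities of the previous level, slice the gene accordingly, then wire
    children positionally. Returns (nested-tuple tree, expressed_length)
    where a node is (symbol, (child, ...)).
    """
    symbols = gene.head + gene.tail
    levels = [[0]]
    consumed = 1
    while True:
        width = sum(functions.arity(symbols[p]) for p in levels[-1])
        if width == 0:
            break
        levels.append(list(range(consumed, consumed + width)))
        consumed += width

    children: dict[int, list[int]] = {p: [] for level in levels for p in level}
    for upper, lower in zip(levels, levels[1:]):
        cursor = 0
        for p in upper:
            k = functions.arity(symbols[p])
            children[p] = lower[cursor : cursor + k]
            cursor += k

    def build(p: int):
        return (symbols[p], tuple(build(c) for c in children[p]))

    return build(0), consumed


def tree_as_tuples(node):
    """Convert a dgselect TreeNode into the oracle's nested-tuple shape."""
    return (node.symbol, tuple(tree_as_tuples(c) for c in node.children))
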