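"""Shared fixtures: the benchmark family is generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from specmap import (
    build_network,
    build_numbering_map,
    cma_matrix,
    generate_family,
    henikoff_weights,
    select_positions,
)
from specmap.family_io import AMINO_ACIDS, Alignment
from specmap.simulate import gh65_analog_spec


@pytest.fixture(scope="session")
def analog():
    """The shipped 22-subgroup benchmark family plus its CMA products."""
    spec = gh65_analog_spec()
    aln, tree, part, truth = generate_family(spec)
    num = build_numbering_map(aln, spec.reference_id)
    w = henikoff_weights(aln)
    cr = cma_matrix(aln, w, numbering=num)
    net = build_network(cr, 0.8)
    sel = select_positions(net, cr)
    return {
        "spec": spec, "aln": aln, "tree": tree, "part": part, "truth": truth,
        "numbering": num, "weights": w, "cr": cr, "net": net, "sel": sel,
    }


def random_alignment(rng: np.random.Generator, n: int, m: int,
                     gap_rate: float = 0.0) -> Alignment:
    cells = rng.integers(0, 20, size=(n, m))
    aa = np.array(list(AMINO_ACIDS))
    chars = aa[cells]
    if gap_rate > 0:
        chars[rng.random((n, m)) < gap_rate] = "-"
    return Alignment(
        ids=tuple(f"s{i}" for i in range(n)),
        rows=tuple("".join(r) for r in chars),
    )
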