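import numpy as np
import pytest

from hallmarkmap.hallmark_db import (
    AnnotationRecord,
    GOTermRef,
    expand_terms,
    load_hallmark_definitions,
)


@pytest.fixture(scope="session")
def default_defs():
    return load_hallmark_definitions()


@pytest.fixture(scope="session")
def term_pools(default_defs):
    """hallmark_id -> sorted expanded label list, for planting annotations."""
    return {d.hallmark_id: sorted(expand_terms(d)) for d in default_defs}


def make_annotations(rng: np.random.Generator, n: int, term_pools, decoys=("decoy process a", "decoy process b")):
    """Random annotation records with terms planted from known hallmark pools."""
    records = []
    hids = sorted(term_pools)
    for i in range(n):
        k = int(rng.integers(0, 4))
        chosen = rng.choice(hids, size=k, replace=False)
        labels = []
        for h in chosen:
            pool = term_pools[int(h)]
            labels.append(pool[int(rng.integers(0, len(pool)))])
        if rng.random() < 0.5:
            labels.append(decoys[int(rng.integers(0, len(decoys)))])
        records.append(
            AnnotationRecord(
                accession=f"P{i:05d}",
                gene=f"G{i:04d}",
                go_terms=frozenset(GOTermRef(term_label=t) for t in labels),
                membrane_flag=bool(rng.random() < 0.4),
            )
        )
    return records
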