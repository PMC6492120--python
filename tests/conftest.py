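import numpy as np
import pandas as pd
import pytest

from ecomorph import SpecimenTable, parse_newick


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree_12():
    return parse_newick("(" + ",".join(f"t{i+1}:1" for i in range(12)) + ");")


@pytest.fixture
def balanced_table():
    """Two species, two specimens per sex, two traits, no missing cells."""
    rows = []
    vals = iter(range(1, 17))
    for sp in ("A", "B"):
        for sex in ("female", "female", "male", "male"):
            rows.append(
                dict(
                    specimen_id=f"{sp}{len(rows)}",
                    species=sp,
                    sex=sex,
                    age_class="adult",
                    provenance="wild",
                    latitude=float(len(rows)),
                    longitude=float(len(rows)),
                    m1=float(next(vals)),
                    m2=float(next(vals)),
                )
            )
    return SpecimenTable(pd.DataFrame(rows), ["m1", "m2"])


def pectinate_newick(n: int) -> str:
    """Ultrametric ladder (maximally imbalanced) tree of depth 1."""
    s = np.linspace(0, 1, n)
    core = f"(t{n-1}:{1-s[n-2]:.8f},t{n}:{1-s[n-2]:.8f})"
    for k in range(n - 3, -1, -1):
        core = f"(t{k+1}:{1-s[k]:.8f},{core}:{s[k+1]-s[k]:.8f})"
    return core + ";"
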