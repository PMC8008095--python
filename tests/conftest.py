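import pytest
from hypothesis import HealthCheck, settings, strategies as st

from gangliosim import (Network, SimulationConfig, Structure, default_ruleset,
                        expand_network, reference_enumeration)
from gangliosim.structures import FILL_ANOMER, Residue

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wild_type() -> Network:
    """The default expansion from bare ceramide."""
    return expand_network(SimulationConfig())


@pytest.fixture(scope="session")
def reference() -> Network:
    return reference_enumeration()


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


# -- random grammar-valid trees ---------------------------------------------

@st.composite
def residue_trees(draw, max_depth: int = 3) -> Residue:
    """A random valid (not necessarily ganglioside-classifiable) subtree."""
    code = draw(st.sampled_from("GLSV"))
    anomer = draw(st.sampled_from(["a", "b", None]))
    res = Residue(code, anomer or FILL_ANOMER[code])
    if max_depth > 0:
        n_children = draw(st.integers(0, 2 if max_depth > 1 else 1))
        linkages = draw(st.lists(st.integers(1, 9), min_size=n_children,
                                 max_size=n_children, unique=True))
        chain_allowed = True
        for linkage in linkages:
            child = draw(residue_trees(max_depth=max_depth - 1))
            child.linkage = linkage
            child.is_branch = not chain_allowed or draw(st.booleans())
            chain_allowed = chain_allowed and child.is_branch
            res.children.append(child)
    return res


@st.composite
def structures(draw) -> Structure:
    """A random grammar-valid structure rooted at ceramide."""
    root = Residue("T")
    if draw(st.booleans()):
        child = draw(residue_trees())
        child.linkage = None
        child.is_branch = False
        root.children.append(child)
    return Structure(root)
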