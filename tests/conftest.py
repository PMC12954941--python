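import pytest

import hiddenproj as hp


@pytest.fixture(scope="session")
def oa12():
    """12-run, 6-factor strength-2 OA from the Paley q=11 Hadamard matrix."""
    return hp.hadamard_to_oa(hp.paley_type1(11), 6)


@pytest.fixture(scope="session")
def oa28():
    """28-run, 6-factor strength-2 OA from the Paley type-II q=13 matrix."""
    return hp.hadamard_to_oa(hp.paley_type2(13), 6)


@pytest.fixture(scope="session")
def oa420():
    """420-run, 16-factor OA from the Paley q=419 matrix."""
    return hp.hadamard_to_oa(hp.paley_type1(419), 16)


@pytest.fixture(scope="session")
def quit_gen():
    return hp.GeneratorSet.from_strings(4, "E=ABC,F=ACD")


@pytest.fixture(scope="session")
def regular16(quit_gen):
    """16-run 2^(6-2) fraction with E=ABC, F=ACD (resolution IV)."""
    return hp.build_regular(quit_gen)


@pytest.fixture(scope="session")
def regular32():
    """32-run 2^(6-1) half fraction with F=ABCDE (resolution VI)."""
    return hp.build_regular(hp.GeneratorSet.from_strings(5, "F=ABCDE"))


@pytest.fixture(scope="session")
def aliased16():
    """16-run fraction with E=AB, F=AC: E is fully aliased with AB."""
    return hp.build_regular(hp.GeneratorSet.from_strings(4, "E=AB,F=AC"))


@pytest.fixture(scope="session")
def full8():
    """2^3 full factorial."""
    return hp.build_regular(hp.GeneratorSet(3))
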