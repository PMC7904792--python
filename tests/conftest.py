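import hypothesis
import pytest

from cpgc import Congener

hypothesis.settings.register_profile(
    "cpgc", derandomize=True, deadline=None, max_examples=60
)
hypothesis.settings.load_profile("cpgc")


# the 25 analytical standards used as real-world congener probes
STANDARD_NAMES = [
    "2,5,6,9-C10Cl4", "1,2,5,6,9,10-C10Cl6", "2,3,4,5,6,7,8,9-C10Cl8",
    "1,1,1,3-C10Cl4", "1,1,1,3-C11Cl4", "1,1,1,3-C12Cl4", "1,1,1,3-C13Cl4",
    "1,1,1,3-C14Cl4", "1,1,1,3,9,10-C10Cl6", "1,1,1,3,10,11-C11Cl6",
    "1,1,1,3,11,12-C12Cl6", "1,1,1,3,12,13-C13Cl6", "1,1,1,3,8,10,10,10-C10Cl8",
    "1,1,1,3,9,11,11,11-C11Cl8", "1,1,1,3,10,12,12,12-C12Cl8",
    "1,1,1,3,11,13,13,13-C13Cl8", "1,1,1,3,12,14,14,14-C14Cl8",
    "1,2,9,10-C10Cl4", "1,2,10,11-C11Cl4", "1,2,13,14-C14Cl4",
    "1,2,3,4,5,6-C11Cl6", "4,5,7,8-C11Cl4", "2,3,4,5-C10Cl4",
    "2,3,4,5-C12Cl4", "1,5,5,6,6,10-C10Cl6",
]


@pytest.fixture(scope="session")
def standard_names() -> list[str]:
    return list(STANDARD_NAMES)


def all_valid_patterns(chain_length: int, max_cl: int):
    """Yield every valid Cl-count vector for the chain (1..max_cl chlorines)."""
    import itertools

    caps = [
        3 if p in (1, chain_length) else 2 for p in range(1, chain_length + 1)
    ]
    for combo in itertools.product(*(range(c + 1) for c in caps)):
        if 1 <= sum(combo) <= max_cl:
            yield Congener(
                chain_length,
                tuple((p, c) for p, c in enumerate(combo, start=1) if c),
            )
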