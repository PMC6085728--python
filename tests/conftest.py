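import pytest

from prismlogic.logic import builtin_gates
from prismlogic.strand_model import ArchitectureSpec, build_canonical_strands


@pytest.fixture(scope="session")
def arch():
    return ArchitectureSpec()


@pytest.fixture(scope="session")
def registry(arch):
    return build_canonical_strands(arch)[0]


@pytest.fixture(scope="session")
def strands(arch):
    return build_canonical_strands(arch)[1]


@pytest.fixture(scope="session")
def gates():
    return builtin_gates()
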