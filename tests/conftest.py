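from dataclasses import replace

import pytest

from mrdeye import SyntheticEyeSpec, render_eye


@pytest.fixture(scope="session")
def default_spec() -> SyntheticEyeSpec:
    return SyntheticEyeSpec()


@pytest.fixture(scope="session")
def noiseless_eye(default_spec):
    """Default noiseless render: 640x480, 12 px/mm, true MRD1 = 3.0 mm."""
    return render_eye(default_spec)


@pytest.fixture()
def make_eye():
    """Factory: render with field overrides on the default spec."""

    def _make(**overrides):
        return render_eye(replace(SyntheticEyeSpec(), **overrides))

    return _make
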