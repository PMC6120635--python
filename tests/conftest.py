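import pytest

import dropclone as dc


@pytest.fixture(scope="session")
def panel_p1() -> dc.AmpliconPanel:
    """Compact AML-style panel: 2 control SNVs + TP53/DNMT3A SNVs + FLT3 ITD."""
    return dc.example_panel(n_amplicons=8, patient=1)


@pytest.fixture(scope="session")
def panel_p2() -> dc.AmpliconPanel:
    """Compact panel with IDH2/NRAS/ASXL1 analysis SNVs."""
    return dc.example_panel(n_amplicons=8, patient=2)


@pytest.fixture(scope="session")
def whitelist() -> dc.BarcodeWhitelist:
    return dc.random_whitelist(6000, seed=3)
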