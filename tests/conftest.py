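import pytest

from panelscope.panel_registry import default_panel_path, load_panel
from panelscope.triage import default_ruleset_path, load_ruleset


@pytest.fixture(scope="session")
def panel():
    return load_panel(default_panel_path())


@pytest.fixture(scope="session")
def protein_panel(panel):
    """The shipped panel restricted to entries carrying a protein form."""
    from panelscope.panel_registry import PanelDefinition

    return PanelDefinition(
        name=panel.name + "-protein-only",
        version=panel.version,
        variants=tuple(v for v in panel.variants if v.descriptor.protein is not None),
    )


@pytest.fixture(scope="session")
def rules():
    return load_ruleset(default_ruleset_path())
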