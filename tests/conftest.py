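"""Shared fixtures: a small hand-built panel and the full synthetic one."""

import pytest

from panelrp.panel_io import Config, GeneInfo, Panel, TargetRegion
from panelrp import synthetic_data


@pytest.fixture(scope="session")
def tiny_panel() -> Panel:
    """Hand-laid mini panel: 5 disease genes, 14 targets, one whitelist site.

    Coordinates are 0-based half-open with the 20 bp flank already baked in
    (coding part is [start+20, end-20)).
    """
    genes = {
        "EYS": GeneInfo("EYS", frozenset({"AR"})),
        "USH2A": GeneInfo("USH2A", frozenset({"AR"})),
        "CEP290": GeneInfo("CEP290", frozenset({"AR"})),
        "RP1": GeneInfo("RP1", frozenset({"AR", "AD"}), ad_hotspot=(500, 1053)),
        "RP2": GeneInfo("RP2", frozenset({"XL"})),
    }
    regions = [
        TargetRegion("chr6", 1000, 1340, "EYS", "EYS_ex1"),
        TargetRegion("chr6", 5000, 5340, "EYS", "EYS_ex13"),
        TargetRegion("chr6", 6000, 6340, "EYS", "EYS_ex14"),
        TargetRegion("chr6", 9000, 9340, "EYS", "EYS_ex19"),
        *[TargetRegion("chr1", 1000 * i, 1000 * i + 340, "USH2A", f"USH2A_ex{44 + i}")
          for i in range(1, 6)],  # ex45..ex49
        TargetRegion("chr12", 1000, 1340, "CEP290", "CEP290_ex5"),
        TargetRegion("chr12", 2000, 2340, "CEP290", "CEP290_ex6"),
        TargetRegion("chr12", 8000, 8050, "CEP290", "CEP290_di1",
                     "deep_intronic_whitelist"),
        TargetRegion("chr8", 2000, 2340, "RP1", "RP1_ex4"),
        TargetRegion("chrX", 500, 840, "RP2", "RP2_ex1"),
    ]
    return Panel(regions, genes, flank_bp=20)


@pytest.fixture(scope="session")
def tiny_config() -> Config:
    return Config(deep_intronic_whitelist=[("CEP290", "chr12", 8026)])


@pytest.fixture(scope="session")
def full_panel():
    panel, whitelist = synthetic_data.build_panel()
    return panel, whitelist
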