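"""glycotopo: mapping glycosylation sites onto membrane-protein topology.

Pipeline stages: tabular I/O (:mod:`glycotopo.io_annotations`), interval
classification against TM annotations (:mod:`glycotopo.topology_mapping`),
structural re-validation against membrane-positioned coordinates
(:mod:`glycotopo.structure_validation`), multi-predictor consensus
(:mod:`glycotopo.consensus_topology`), seeded synthetic fixtures
(:mod:`glycotopo.synthetic_data`) and summary reporting
(:mod:`glycotopo.report`).
"""

from importlib import resources
from pathlib import Path

__version__ = "0.1.0"

FIXTURE_NAMES = (
    "table1_sites.tsv",
    "table2_interface_O.tsv",
    "table3_interface_N.tsv",
    "topology.tsv",
)


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture table."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return Path(resources.files("glycotopo").joinpath("fixtures", name))
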