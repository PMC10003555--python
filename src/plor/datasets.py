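"""Packaged example data: the pbuE adenine riboswitch PLOR system.

The bundled template is the 155-nt dsDNA used to transcribe the Bacillus
subtilis pbuE adenine riboswitch (T7 promoter on the reverse complement of
the printed strand; 120-nt run-off transcript; intrinsic terminator U-tract
giving a 100-nt terminated product), together with its 8-step
pause-restart schedule.
"""

from __future__ import annotations

from importlib import resources

from .schedule_design import Schedule, schedule_from_dict
from .sequence_core import NucleicSequence, normalize_sequence

import yaml

_TEMPLATE_RESOURCE = "pbuE_riboswitch_template.fa"
_SCHEDULE_RESOURCE = "eight_step_schedule.yaml"


def template_path() -> str:
    """Filesystem path of the packaged template FASTA."""
    return str(resources.files("plor.data") / _TEMPLATE_RESOURCE)


def schedule_path() -> str:
    """Filesystem path of the packaged 8-step schedule YAML."""
    return str(resources.files("plor.data") / _SCHEDULE_RESOURCE)


def riboswitch_template() -> NucleicSequence:
    """The pbuE adenine riboswitch dsDNA template (printed strand)."""
    text = (resources.files("plor.data") / _TEMPLATE_RESOURCE).read_text()
    body = "".join(line for line in text.splitlines() if not line.startswith(">"))
    return normalize_sequence(body, "DNA")


def eight_step_schedule() -> Schedule:
    """The 8-step pause-restart schedule for the riboswitch template."""
    cfg = yaml.safe_load((resources.files("plor.data") / _SCHEDULE_RESOURCE).read_text())
    return schedule_from_dict(cfg)
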