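import pytest

from plor import datasets, derive_transcript


@pytest.fixture(scope="session")
def template():
    """The packaged pbuE adenine riboswitch dsDNA template (155 nt)."""
    return datasets.riboswitch_template()


@pytest.fixture(scope="session")
def transcript(template):
    """Its 120-nt run-off transcript."""
    return derive_transcript(template)


@pytest.fixture(scope="session")
def eight_step(transcript):
    """The packaged 8-step pause-restart schedule (5 uM DNA)."""
    return datasets.eight_step_schedule()
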