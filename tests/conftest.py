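import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def toy_transcript_tsv() -> str:
    """Three-turn toy session: one interviewer question between two answers."""
    return (
        "start_time\tstop_time\tspeaker\tvalue\n"
        "0.0\t1.0\tParticipant\thello there\n"
        "2.0\t3.0\tEllie\thow are you doing today\n"
        "4.0\t5.0\tParticipant\tpretty good thanks\n"
    )


@pytest.fixture
def session_transcript_tsv() -> str:
    """[Q1, A, A, Q2, A] session used for the pairing examples."""
    return (
        "start_time\tstop_time\tspeaker\tvalue\n"
        "0.0\t1.0\tEllie\thow are you doing today\n"
        "2.0\t3.0\tParticipant\ti'm fine\n"
        "4.0\t5.0\tParticipant\tmostly\n"
        "6.0\t7.0\tEllie\thow have you been sleeping\n"
        "8.0\t9.0\tParticipant\tnot great lately\n"
    )
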