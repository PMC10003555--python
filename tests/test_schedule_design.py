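"""Halting rule, segment tiling, stoichiometric batches, inverse label design."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plor import (
    Explicit,
    LabelDesignError,
    NucleicSequence,
    Schedule,
    ScheduleError,
    StepSpec,
    Stoichiometric,
    Transcript,
    batch_for_segment,
    build_segments,
    design_even_schedule,
    design_label_schedule,
    design_sheet,
    find_t7_promoter,
    halt_position,
    schedule_from_dict,
    validate_schedule,
)
from plor.sequence_core import T7_PROMOTER


def make_tx(rna: str) -> Transcript:
    site = find_t7_promoter(NucleicSequence(T7_PROMOTER + "G", "DNA"))
    return Transcript(rna=NucleicSequence(rna, "RNA"), source_site=site)


def make_schedule(subsets, dna=5.0, fold=1.0):
    return Schedule(
        steps=tuple(
            StepSpec(index=i, included=frozenset(s), amount_policy=Stoichiometric(fold))
            for i, s in enumerate(subsets, 1)
        ),
        dna_conc=dna,
    )


EIGHT_SUBSETS = ["AGU", "ACU", "AGU", "ACU", "ACG", "ACU", "AGU", "ACGU"]


# --- halting rule ---------------------------------------------------------

def test_halt_position_on_riboswitch_transcript(transcript):
    assert halt_position(transcript, 1, set("AGU")) == 14  # first C at 15
    assert halt_position(transcript, 15, set("ACU")) == 26  # next G at 27
    assert halt_position(transcript, 1, set("ACGU")) == transcript.length
    assert halt_position(transcript, 15, set("G")) == 14  # zero progress


def test_halt_position_rejects_out_of_range(transcript):
    with pytest.raises(ScheduleError):
        halt_position(transcript, 0, set("ACGU"))
    with pytest.raises(ScheduleError):
        halt_position(transcript, transcript.length + 2, set("ACGU"))


# --- segment tiling -------------------------------------------------------

def test_eight_step_boundaries(transcript, eight_step):
    segs = build_segments(transcript, eight_step)
    assert [(s.start, s.end) for s in segs] == [
        (1, 14), (15, 26), (27, 39), (40, 45),
        (46, 52), (53, 61), (62, 66), (67, 120),
    ]
    assert sum(s.length for s in segs) == transcript.length
    for s in segs:
        assert sum(s.composition.values()) == s.length


def test_build_segments_trivial_and_errors():
    tx = make_tx("GGGA")
    segs = build_segments(tx, make_schedule(["G", "AG"]))
    assert [(s.start, s.end) for s in segs] == [(1, 3), (4, 4)]
    with pytest.raises(ScheduleError, match="stalled step 1"):
        build_segments(tx, make_schedule(["A", "AG"]))
    with pytest.raises(ScheduleError, match="incomplete schedule, stopped at 3"):
        build_segments(tx, make_schedule(["G"]))
    assert len(build_segments(tx, make_schedule(["G"]), allow_partial=True)) == 1


def _oracle_segments(rna, subsets):
    """Per-base reference simulation: advance one base while incorporable."""
    segs, pos = [], 1
    for k, inc in enumerate(subsets, 1):
        start = pos
        while pos <= len(rna) and rna[pos - 1] in inc:
            pos += 1
        if pos == start:
            return segs, ("stall", k)
        segs.append((start, pos - 1))
        if pos > len(rna):
            return segs, ("complete", None)
    return segs, ("incomplete", pos - 1)


def _random_case(rng):
    rna = "".join(rng.choice("ACGU") for _ in range(rng.randint(1, 200)))
    subsets = [
        frozenset(rng.sample("ACGU", rng.randint(1, 4)))
        for _ in range(rng.randint(1, 10))
    ]
    return rna, subsets


def _compare_with_oracle(rna, subsets):
    tx = make_tx(rna)
    sched = make_schedule(subsets)
    expected, (status, _detail) = _oracle_segments(rna, subsets)
    if status == "stall":
        with pytest.raises(ScheduleError, match="stalled"):
            build_segments(tx, sched, allow_partial=True)
        return
    got = build_segments(tx, sched, allow_partial=True)
    assert [(s.start, s.end) for s in got] == expected
    if status == "incomplete":
        with pytest.raises(ScheduleError, match="incomplete"):
            build_segments(tx, sched, allow_partial=False)


def test_build_segments_matches_per_base_oracle_bulk():
    rng = random.Random(42)
    for _ in range(1000):
        _compare_with_oracle(*_random_case(rng))


@settings(max_examples=200, derandomize=True)
@given(
    st.text(alphabet="ACGU", min_size=1, max_size=80),
    st.lists(
        st.frozensets(st.sampled_from("ACGU"), min_size=1, max_size=4),
        min_size=1,
        max_size=8,
    ),
)
def test_tiling_is_contiguous_and_conserving(rna, subsets):
    tx = make_tx(rna)
    try:
        segs = build_segments(tx, make_schedule(subsets), allow_partial=True)
    except ScheduleError:
        return
    pos = 1
    for s in segs:
        assert s.start == pos
        assert s.end >= s.start
        pos = s.end + 1
    assert sum(s.length for s in segs) == segs[-1].end


# --- stoichiometry --------------------------------------------------------

def test_batches_scale_linearly_in_fold(transcript, eight_step):
    segs = build_segments(transcript, eight_step)
    seg8, step8 = segs[7], eight_step.steps[7]
    base = batch_for_segment(seg8, eight_step, step8)
    for fold in (0.5, 2.0, 10.0):
        scaled_step = StepSpec(
            index=8, included=step8.included, amount_policy=Stoichiometric(fold)
        )
        scaled = batch_for_segment(seg8, eight_step, scaled_step)
        for b in "ACGU":
            assert scaled.conc[b] == pytest.approx(fold * base.conc[b])


def test_explicit_policy_passes_through(transcript, eight_step):
    segs = build_segments(transcript, eight_step)
    batch = batch_for_segment(segs[0], eight_step, eight_step.steps[0])
    assert batch.conc == {"A": 400.0, "C": 0.0, "G": 600.0, "U": 64.0}
    assert batch.fold is None


def test_zero_length_segment_gives_zero_batch(transcript, eight_step):
    from plor import Segment

    empty = Segment(2, 15, 14, {"A": 0, "C": 0, "G": 0, "U": 0})
    batch = batch_for_segment(empty, eight_step, eight_step.steps[1])
    assert all(v == 0 for v in batch.conc.values())


def test_design_sheet_rows_and_product_sizes(transcript, eight_step):
    sheet = design_sheet(transcript, eight_step)
    assert list(sheet["step"]) == list(range(1, 9))
    assert sheet.attrs["full_length_nt"] == 120
    assert sheet.attrs["terminated_nt"] == 100
    row2 = sheet.loc[sheet["step"] == 2].iloc[0]
    assert (row2["ATP_uM"], row2["CTP_uM"], row2["UTP_uM"]) == (25.0, 15.0, 20.0)


def test_single_step_schedule_covers_whole_transcript(transcript):
    sheet = design_sheet(transcript, make_schedule(["ACGU"]))
    assert (sheet.iloc[0]["start"], sheet.iloc[0]["end"]) == (1, transcript.length)


# --- validation -----------------------------------------------------------

def test_validate_schedule_reports(transcript, eight_step):
    report = validate_schedule(transcript, eight_step)
    assert report.complete and report.n_steps == 8
    assert report.warnings == ()

    warned = validate_schedule(transcript, make_schedule(["ACGU", "ACGU"]))
    assert any("step 1 cannot pause" in w for w in warned.warnings)

    stalled = validate_schedule(make_tx("GGGA"), make_schedule(["A", "AG"]))
    assert not stalled.complete and stalled.stalled_at_step == 1


# --- inverse label design -------------------------------------------------

def test_label_design_riboswitch_u41(transcript):
    sched = design_label_schedule(transcript, [41], "U", label_name="Cy3")
    report = validate_schedule(transcript, sched)
    assert report.complete
    segs = build_segments(transcript, sched)
    (label_step,) = [s for s in sched.steps if s.label_substitution]
    seg = segs[label_step.index - 1]
    assert seg.composition["U"] == 1
    assert transcript.rna.residues[40] == "U"  # position 41 really is U
    assert seg.start <= 41 <= seg.end


def test_label_design_trivial_two_step():
    sched = design_label_schedule(make_tx("GGGAU"), [5], "U")
    assert len(sched) == 2
    assert sorted(sched.steps[0].included) == ["A", "G"]
    assert sched.steps[1].label_substitution == ("U", "label")
    assert sched.steps[1].included == frozenset("ACGU")


def test_label_design_infeasible_consecutive_base():
    with pytest.raises(LabelDesignError, match="label not isolatable at 4"):
        design_label_schedule(make_tx("GGGUU"), [4], "U")


def test_label_design_rejects_wrong_base_or_position(transcript):
    with pytest.raises(LabelDesignError, match="not U"):
        design_label_schedule(transcript, [1], "U")  # position 1 is G
    with pytest.raises(LabelDesignError, match="outside transcript"):
        design_label_schedule(transcript, [500], "U")


def test_label_design_greedy_matches_exhaustive_step_count():
    """Greedy and BFS-exhaustive designs use the same (minimal) step count."""
    rng = random.Random(99)
    compared = 0
    for _ in range(200):
        rna = "".join(rng.choice("ACGU") for _ in range(rng.randint(4, 40)))
        base = rng.choice("ACGU")
        positions = [i + 1 for i, c in enumerate(rna) if c == base]
        if not positions:
            continue
        target = [rng.choice(positions)]
        try:
            greedy = design_label_schedule(make_tx(rna), target, base, method="greedy")
        except LabelDesignError:
            with pytest.raises(LabelDesignError):
                design_label_schedule(make_tx(rna), target, base, method="exhaustive")
            continue
        exhaustive = design_label_schedule(make_tx(rna), target, base, method="exhaustive")
        assert len(greedy) == len(exhaustive)
        compared += 1
    assert compared > 50


@settings(max_examples=150, derandomize=True)
@given(st.data())
def test_label_design_output_is_valid_and_isolates_label(data):
    rna = data.draw(st.text(alphabet="ACGU", min_size=3, max_size=60))
    positions = [i + 1 for i, c in enumerate(rna) if c == "U"]
    if not positions:
        return
    target = data.draw(st.sampled_from(positions))
    tx = make_tx(rna)
    try:
        sched = design_label_schedule(tx, [target], "U")
    except LabelDesignError:
        return
    report = validate_schedule(tx, sched)
    assert report.complete
    segs = build_segments(tx, sched)
    (label_step,) = [s for s in sched.steps if s.label_substitution]
    assert segs[label_step.index - 1].composition["U"] == 1
    assert sched.steps[-1].included == frozenset("ACGU")


# --- even-schedule construction & config ----------------------------------

@pytest.mark.parametrize("k", [1, 3, 6, 8, 10])
def test_design_even_schedule_is_complete(transcript, k):
    sched = design_even_schedule(transcript, k)
    assert len(sched) == k
    assert validate_schedule(transcript, sched).complete
    segs = build_segments(transcript, sched)
    assert segs[-1].end == transcript.length


def test_schedule_from_dict_roundtrip():
    sched = schedule_from_dict(
        {
            "dna_uM": 5,
            "steps": [
                {"included": ["A", "G", "U"], "explicit": {"A": 400, "G": 600, "U": 64}},
                {"included": ["A", "C", "U"], "fold": 2.0,
                 "label": {"base": "U", "name": "Cy3"},
                 "condition": {"Mg_mM": 6}},
            ],
        }
    )
    assert isinstance(sched.steps[0].amount_policy, Explicit)
    assert sched.steps[1].amount_policy == Stoichiometric(2.0)
    assert sched.steps[1].label_substitution == ("U", "Cy3")
    assert sched.steps[1].condition["Mg_mM"] == 6


def test_schedule_validation_errors():
    with pytest.raises(ScheduleError, match="consecutive"):
        Schedule(steps=(StepSpec(index=2, included=frozenset("A")),))
    with pytest.raises(ScheduleError, match="label base"):
        StepSpec(index=1, included=frozenset("AG"), label_substitution=("U", "Cy3"))
    with pytest.raises(ScheduleError, match="fold"):
        Stoichiometric(0)
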