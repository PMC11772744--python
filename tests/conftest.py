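import pytest

from nirsbids.synth import MontageSpec, StudySpec, TaskSpec, generate_recording, generate_study


@pytest.fixture
def small_spec() -> StudySpec:
    """Two participants, tiny 2-D template montage, two conditions — fast."""
    return StudySpec(
        name="small study",
        n_participants=2,
        montage_spec=MontageSpec(2, 2, 3, 1, coordinate_kind="template2d"),
        task_spec=TaskSpec(
            name="task",
            conditions=("a", "b"),
            block_duration_s=3.0,
            inter_block_interval_s=2.0,
            n_blocks_per_condition=1,
        ),
        fs=5.0,
        seed=7,
    )


@pytest.fixture
def small_spec_3d(small_spec) -> StudySpec:
    from dataclasses import replace

    return replace(
        small_spec,
        montage_spec=replace(small_spec.montage_spec, coordinate_kind="measured3d"),
    )


@pytest.fixture
def small_recording(small_spec):
    return generate_recording(small_spec, 0)


@pytest.fixture
def small_tree(tmp_path, small_spec):
    root = tmp_path / "dataset"
    generate_study(small_spec, root)
    return root
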