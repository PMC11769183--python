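import numpy as np
import pytest

from fatiguecg import features as ft
from fatiguecg import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort() -> list[syn.ECGRecord]:
    """Four subjects, 30 s each — enough for pipeline plumbing tests."""
    return syn.generate_cohort(4, duration_s=30.0, seed=7)


def make_toy_examples(
    n: int, seed: int = 0, shift: float = 3.0, img_shape: tuple[int, int] = (17, 25)
) -> list[ft.Example]:
    """Trivially separable labeled examples for classifier plumbing tests.

    Class F gets a +shift offset on both the signal and the images, class N a
    -shift offset, on top of unit white noise.
    """
    rng = np.random.default_rng(seed)
    examples = []
    for i in range(n):
        label = "F" if i % 2 == 0 else "N"
        offset = shift if label == "F" else -shift
        profile = syn.SubjectProfile(f"T{i:02d}", 20 + (i % 8), syn.GENDERS[i % 2], label)
        signal = rng.normal(size=ft.SEGMENT_LENGTH * ft.GROUP_SIZE) + offset
        segments = ft.segment_signal(signal, record_id=profile.subject_id)
        group = ft.SegmentGroup(tuple(segments), label, profile)
        images = rng.normal(size=(ft.GROUP_SIZE, *img_shape)) + offset
        examples.append(ft.Example(group=group, images=images, label=label))
    return examples


@pytest.fixture
def toy_examples() -> list[ft.Example]:
    return make_toy_examples(16)
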