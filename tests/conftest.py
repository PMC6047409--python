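import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from capwin.experiment import ExperimentMatrix, SampleInfo
from capwin.windows import GenomicWindow, TargetClass, WindowSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_experiment(counts, treatments=None, target_classes=None, chroms=None):
    """Build an ExperimentMatrix from a plain count array.

    treatments: list of treatment names per column (default: two halves,
    'control' then 'treatment'). target_classes: per-row class strings.
    """
    counts = np.asarray(counts)
    n_w, n_s = counts.shape
    if treatments is None:
        half = n_s // 2
        treatments = ["control"] * half + ["treatment"] * (n_s - half)
    reps = {}
    samples = []
    for j, t in enumerate(treatments):
        reps[t] = reps.get(t, 0) + 1
        samples.append(SampleInfo(f"{t}_{reps[t]}", t, reps[t]))
    if target_classes is None:
        target_classes = ["on_target"] * n_w
    if chroms is None:
        chroms = ["chr1"] * n_w
    windows = WindowSet(
        GenomicWindow(
            chroms[i], 100 * i, 100 * i + 50, f"w{i:03d}",
            TargetClass(target_classes[i]),
        )
        for i in range(n_w)
    )
    return ExperimentMatrix(windows, samples, counts)


@pytest.fixture
def small_experiment():
    """4 windows x 4 samples (2 control, 2 treatment), mixed target classes."""
    counts = np.array(
        [
            [10, 12, 11, 9],
            [100, 110, 95, 105],
            [5, 0, 7, 3],
            [50, 55, 48, 52],
        ]
    )
    return make_experiment(
        counts,
        target_classes=["on_target", "on_target", "off_target", "control"],
    )


def write_bam(path, reads, chrom_lengths):
    """Write a sorted, indexed BAM from (qname, chrom, pos, mapq, flag, tlen,
    mate_pos) tuples; all reads are 50 bp matches."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": length}
            for name, length in chrom_lengths.items()
        ],
    }
    chrom_ids = {name: i for i, name in enumerate(chrom_lengths)}
    reads = sorted(reads, key=lambda r: (chrom_ids[r[1]], r[2]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for qname, chrom, pos, mapq, flag, tlen, mate_pos in reads:
            a = pysam.AlignedSegment()
            a.query_name = qname
            a.query_sequence = "A" * 50
            a.query_qualities = pysam.qualitystring_to_array("I" * 50)
            a.reference_id = chrom_ids[chrom]
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = "50M"
            a.flag = flag
            a.template_length = tlen
            if mate_pos is not None:
                a.next_reference_id = chrom_ids[chrom]
                a.next_reference_start = mate_pos
            bam.write(a)
    pysam.index(str(path))
    return path
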