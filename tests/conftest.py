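import numpy as np
import pytest

from repeatmeth import LengthLaw, SimulationConfig, build_locus

NO_ERROR = (0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def locus():
    """Small locus: 300-nt flanks, 20 CpG sites, CTG motif."""
    return build_locus(flank_length=300, n_cpg=20, motif="CTG", seed=11)


@pytest.fixture(scope="session")
def island_locus():
    """CpG-island-scale locus: 2000-nt flanks, 400 CpG sites."""
    return build_locus(flank_length=2000, n_cpg=400, motif="CTG", seed=11)


def clean_config(seed=0, n_reads=20, count=500, **kw):
    """Zero-noise, no-bias config with a fixed expanded length."""
    defaults = dict(
        seed=seed,
        n_reads=n_reads,
        error_rates=NO_ERROR,
        length_bias=0.0,
        expanded_length_law=LengthLaw(family="fixed", median=count),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def brute_force_count(sequence, locus):
    """Independent repeat-count oracle for error-free reads.

    Finds the exact 150-nt flank anchors by substring search (trying both
    orientations) and counts the longest run of exact motif copies between
    them.  Returns None when the anchors are absent.
    """
    from repeatmeth import reverse_complement

    for seq in (sequence, reverse_complement(sequence)):
        i = seq.find(locus.prefix_anchor)
        j = seq.find(locus.suffix_anchor)
        if i < 0 or j < 0:
            continue
        tract = seq[i + len(locus.prefix_anchor) : j]
        run = best = 0
        for k in range(0, len(tract) - 2, 3):
            if tract[k : k + 3] == locus.motif:
                run += 1
                best = max(best, run)
            else:
                run = 0
        return best
    return None


def rng(seed=0):
    return np.random.default_rng(seed)
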