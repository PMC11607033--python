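import numpy as np


def chain_generator(rates):
    """Absorbing-chain generator: state i feeds state i+1 at the given rate.

    Equal consecutive rates produce non-trivial Jordan blocks in the
    exponential, making these the canonical defective test matrices.
    """
    d = len(rates) + 1
    q = np.zeros((d, d))
    for i, r in enumerate(rates):
        q[i, i] = -r
        q[i, i + 1] = r
    return q


def best_recovery(result, q_true):
    """Smallest max-norm distance between a returned generator and the truth."""
    return min((np.abs(g - q_true).max() for g in result.generators),
               default=np.inf)
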