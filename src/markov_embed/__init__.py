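"""markov_embed: the embedding problem for Markov matrices with d <= 4.

Decides whether a d-state stochastic matrix (d in {2, 3, 4}) can be
written as ``M = e^Q`` for a Markov generator ``Q`` (classic embedding),
constructs all generators found together with uniqueness certificates, and
handles the time-inhomogeneous generalisation (reachability by a Markov
flow with time-dependent generators) for d = 3.
"""

from __future__ import annotations

import numpy as np

from .embed_d2 import embed_2x2
from .embed_d3 import (
    commutant_basis,
    cyclic_generators,
    delta_min,
    delta_min_cyclic,
    embed_3x3,
    equal_input_negative,
    extremal_generators,
)
from .embed_d4 import embed_4x4
from .fixtures import Fixture, fixture, fixture_names
from .inhomogeneous import (
    GeneratorFamily,
    PBSSolution,
    b_statistic,
    equal_input_g_embeddable,
    g_embeddable_3x3,
    pbs_solve,
    poisson,
    star_shape_deform,
)
from .matrix_core import (
    E_MINUS_2PI_SQRT3,
    E_MINUS_4PI_SQRT3,
    E_MINUS_PI,
    E_MINUS_PI_SQRT3,
    ConditionReport,
    EmbeddingResult,
    MarkovMatrix,
    RateMatrix,
    SearchConfig,
    SpectralSummary,
    ValidationError,
    ZeroRowSumMatrix,
    exp_residual,
    is_generator,
    matrix_exp,
    necessary_conditions,
    principal_log,
    spectral_summary,
    uniqueness_certificates,
    validate_markov,
    validate_rate,
)
from .phylo_models import (
    K3STParams,
    TNParams,
    equal_input_embeddable,
    equal_input_matrix,
    k3st,
    k3st_embeddable,
    k3st_spectrum,
    tamura_nei,
    tn_embeddable,
    tn_spectrum,
)
from .sampling import sample_generator, sample_markov

__version__ = "0.1.0"


def embed(M, **kwargs) -> EmbeddingResult:
    """Dispatch to the d-specific embedding solver by matrix dimension."""
    m = np.asarray(M.entries if isinstance(M, MarkovMatrix) else M, dtype=float)
    d = m.shape[0]
    solvers = {2: embed_2x2, 3: embed_3x3, 4: embed_4x4}
    if d not in solvers:
        raise ValidationError(f"dimension d={d} outside supported range {{2,3,4}}")
    return solvers[d](m, **kwargs)
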