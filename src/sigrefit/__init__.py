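"""sigrefit: sparse mutational-signature refitting with sampling awareness.

Decomposes a tumor's 96-trinucleotide-context mutation spectrum into a
sparse non-negative combination of known signatures by jointly maximizing
the multinomial sampling likelihood of the observed counts and an
L1-penalized linear signature fit, with prior-weighted penalties and
empirical hyperparameter tuning.
"""

__version__ = "0.1.0"

from .contexts import (
    CONTEXT_LABELS,
    InvalidVariantError,
    SubstitutionContext,
    UnclassifiableContextError,
    classify_substitution,
)
from .spectra import (
    MutationSpectrum,
    SignatureCatalog,
    SkipReport,
    read_signature_catalog,
    read_spectrum,
    vcf_to_spectrum,
    write_signature_catalog,
    write_spectrum,
)
from .fitting import (
    FitResult,
    FitSettings,
    NoiseModel,
    PenaltyConfig,
    PStepSolution,
    adaptive_penalties,
    estimate_alpha,
    fit,
    make_prior_penalties,
    p_step,
    tune_lambda,
    w_step,
)
from .simulate import (
    PriorSpec,
    SimulatedSample,
    SupportMetrics,
    mse_weights,
    run_benchmark,
    simulate_sample,
    support_metrics,
    synthetic_catalog,
)

__all__ = [
    "__version__",
    "CONTEXT_LABELS",
    "SubstitutionContext",
    "InvalidVariantError",
    "UnclassifiableContextError",
    "classify_substitution",
    "MutationSpectrum",
    "SignatureCatalog",
    "SkipReport",
    "read_signature_catalog",
    "read_spectrum",
    "vcf_to_spectrum",
    "write_signature_catalog",
    "write_spectrum",
    "FitResult",
    "FitSettings",
    "NoiseModel",
    "PenaltyConfig",
    "PStepSolution",
    "adaptive_penalties",
    "estimate_alpha",
    "fit",
    "make_prior_penalties",
    "p_step",
    "tune_lambda",
    "w_step",
    "PriorSpec",
    "SimulatedSample",
    "SupportMetrics",
    "mse_weights",
    "run_benchmark",
    "simulate_sample",
    "support_metrics",
    "synthetic_catalog",
]

def default_catalog() -> SignatureCatalog:
    """The bundled default catalog: 30 synthetic signatures, COSMIC v2 layout.

    The bundled file is synthetic (generated by :func:`synthetic_catalog`),
    shipped so the tool runs fully offline; supply your own catalog file for
    analyses of real tumors.
    """
    from importlib.resources import files

    path = files("sigrefit.data").joinpath("synthetic_signatures_30.tsv")
    return read_signature_catalog(str(path))
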