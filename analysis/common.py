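"""Shared configuration for the numbered analysis drivers.

The demo cohort: 2,000 samples, 200 genes (three causal, signed effects
+0.6 / -0.5 / +0.4 on the standardised burden), 500 common SNPs (50 causal,
beta ~ N(0, 0.15)), 15% statin users on a cholesterol-like trait. Bulky
intermediates (dosage tables) live under scratch/, small summary tables
under results/.
"""
from pathlib import Path

from burdenblend.io_formats import RunConfig
from burdenblend.synthetic_data import SimulationConfig, pick_causal_genes

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 5

SIM_CONFIG = SimulationConfig(
    n_samples=2000,
    n_genes=200,
    n_common_snps=500,
    causal_genes=pick_causal_genes(200, [0.6, -0.5, 0.4]),
    n_causal_snps=50,
    snp_effect_sd=0.15,
    statin_prevalence=0.15,
    seed=SEED,
)

RUN_CONFIG = RunConfig(random_seed=SEED)

COVARIATES = ["bmi", "age", "sex", "pc1", "pc2", "pc3", "pc4"]


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
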