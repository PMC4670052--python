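# reefsim

Does fish *attraction* to an artificial reef make the stock easier to
overfish? `reefsim` is a spatially discrete simulator for answering that
question for fisheries scientists and reef managers. Deploying an
artificial reef (AR) near existing natural reef (NR) redistributes the
fish biomass that is already there; whether that redistribution
*concentrates* biomass (raising catch rates) or *disperses* it (lowering
them) depends on reef, species and harvest characteristics. The package
simulates that redistribution on a lattice, measures catch per unit
effort (CPUE) before and after deployment, and ranks which parameters
drive the outcome.

## The model

The arena is a 211 × 211 grid of 10 × 10 m cells. Relative biomass around
a reef declines exponentially with distance from the nearest reef cell:

    B_i = exp(-k · D_i),   k = ln 2 / D_h

where `D_h` (**fidelity**) is the distance at which density halves. When
an AR is deployed, each cell gives up a logistic fraction of its biomass:

    B_ri = B_i − B_i · Q0 / (1 + exp((ln 99² / D_99) · (D_i − D_50)))

where `D_50` (**mobility**) is the distance at which half a cell's biomass
relocates, `D_99 = 2·D_50` spans ~99% of the decline, and
`Q0 = Q/(Q+1)` is the limiting attracted proportion implied by the AR:NR
**quality ratio** `Q`. The attracted total is laid back down around the AR
with the same exponential kernel (`B_ai = B_ri + Σ(B_i − B_ri)·w_i`), so
total biomass is conserved — attraction only moves fish.

Two functional groups are supported: **reef residents** (biomass exists
only around reefs) and **reef-associated pelagics** (biomass starts
uniform everywhere and undergoes two rounds of attraction: first to the
NR with quality `Q_nr = 1`, then to the AR).

Harvest follows a gravity model with no uncertainty: fishers always take
the `p` richest cells. `CPUE_b = Σ top-p B_i`, `CPUE_a = Σ top-p B_ai`,
re-selecting cells after deployment, and the ratio `CPUE_a : CPUE_b`
measures exploitation risk (>1 concentration, <1 dispersal). A threshold
catch variant caps per-cell catch at 70% of the pre-deployment maximum
density. A Monte-Carlo sensitivity analysis (2000 iterations per reef
separation stratum, standardized main-effects regression) ranks parameter
importance.

## Worked example

```python
from reefsim import ScenarioParams, run_scenario

params = ScenarioParams(group="pelagic", s_r=3, q=7, d_r_step=3,
                        d_50=200, d_h=10, p=2)
result = run_scenario(params)
print(f"D_r = {result.realized_d_r:.1f} m")
print(f"attracted fraction = {result.attracted_fraction:.4f}")
print(f"CPUE before = {result.harvest.cpue_b:.2f}, "
      f"after = {result.harvest.cpue_a:.2f}, ratio = {result.ratio:.3f}")
```

prints

```
D_r = 127.3 m
attracted fraction = 0.0334
CPUE before = 56.27, after = 168.52, ratio = 2.995
```

A high-quality AR (`Q=7`) deployed 127 m from a 3×3 natural reef nearly
triples the catch rate of a tightly reef-associated (`D_h=10` m) pelagic
species when only the two richest cells are fished — a high-risk
scenario. The same command-line run:

```sh
reefsim scenario --group pelagic --s-r 3 --q 7 --d-r-step 3 \
    --d-50 200 --d-h 10 --p 2
reefsim sweep --preset fig5F --out panels/       # full fidelity × effort panel
reefsim sensitivity --group resident --iters 2000 --seed 42 --out sens/
```

Sweep presets (`fig3A`–`fig5F`, `figS1A`–`figS2F`) reproduce the standard
result panels as tidy CSV tables; `export-field` writes any biomass
surface as a CSV matrix for mapping.

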