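# sarmdyn

Solution-dynamics analysis for a multimeric, allosterically switched enzyme:
the octameric NADase SARM1, whose autoinhibited ("closed", doughnut-shaped)
and activated ("open", blooming) conformations interconvert depending on
which ligand — NAD⁺ (substrate/inhibitor) or NMN (activator) — occupies the
ARM-domain allosteric pocket. The package implements the three desk-scale
computations that characterise this switch:

1. **HDX-MS EX1 deconvolution** (`sarmdyn.hdx`) — centroid deuterium uptake,
   per-timepoint condition differencing with a strict >0.4 Da significance
   rule, shared-width two-Gaussian decomposition of bimodal isotopic
   envelopes, and first-order open↔closed transition kinetics.
2. **Crosslink-to-structure mapping** (`sarmdyn.xlmap`) — placement of
   lysine–lysine crosslink identifications on a multimeric assembly,
   minimum-distance disambiguation of intra- vs intermolecular links,
   satisfaction at a 30 Å Cα–Cα restraint, and a through-domain clash test
   for link vectors that would have to pierce a folded domain.
3. **Rigid-body motion quantification** (`sarmdyn.motion`) — least-squares
   (Kabsch) superposition, selection-restricted RMSD with a separate
   alignment selection, and domain rotation angles with marker-atom
   displacements between ligand-bound states.

A seeded synthetic-data generator (`sarmdyn.synthetic`) emulates every
input — EX1/EX2 isotopic envelopes, a lysine-rich toy ring octamer,
crosslink lists with held-out truth labels, and state pairs related by a
known rigid motion — so the whole pipeline runs and validates with no
downloads.

## The statistics at the core

In the EX1 exchange regime a peptide's isotopic envelope is a mixture of a
low-mass (closed) and a high-mass (open) subpopulation. Each envelope is fit
on the charge-deconvoluted mass axis as

    I(m) = A_low · G(m; μ_low, σ) + A_high · G(m; μ_high, σ),   μ_low < μ_high,

two Gaussian peaks with different means and areas but a shared width. The
open-state fraction is the high-mass area ratio,

    f_open = A_high / (A_low + A_high),

and its time course follows first-order interconversion,

    f(t) = f_inf − (f_inf − f0) · exp(−k_open · t).

Crosslink satisfaction on an assembly of n chains takes, for each
residue-pair identification (i, j), the minimum Cα–Cα distance over all
chain-pair placements; a link is satisfied iff that distance is ≤ 30 Å *and*
the connecting vector is clash-free. Domain motion between states A and B is
the residual rotation of the mobile selection after superposing B on A via
the reference selection; the angle is `arccos((tr R − 1)/2)`.

## Worked example

```
python analysis/01_generate_fixtures.py   # synthetic inputs -> scratch/demo/
python analysis/02_hdx_ex1.py             # uptake, differencing, EX1 kinetics
python analysis/03_map_crosslinks.py      # crosslink mapping + cutoff sweep
python analysis/04_domain_motion.py       # superposition + rotation angle
```

The second script prints (seed 1):

```
EX1 transition kinetics (closed -> open), recovered from envelopes:
  pep_ex1/NAD: k_open = 1.00e-03 /s, f0 = 0.050, f_inf = 0.598
  pep_ex1/NMN: k_open = 1.00e-02 /s, f0 = 0.049, f_inf = 0.899
activator/substrate rate ratio: 10.0x (the activator destabilises the closed state)
```

i.e. the deconvolution recovers, from the raw simulated spectra alone, the
ten-fold faster closed→open conversion that the generator built into the
activator condition. The third script reports

```
mapped 10/10 crosslinks; 80% satisfied at 30 Å
classification matches truth labels for 10/10 records
```

— the 8 true contacts and 2 decoys are classified exactly as generated —
and the fourth recovers the 30.000° rotation applied to the mobile protomer.

The same three analyses are exposed as a CLI over TOML configs:

```
sarmdyn demo --out demo_dir --seed 1
sarmdyn run --config demo_dir/config.toml
```

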