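# stenoflow

Pulsatile, shear-thinning blood flow through an idealized stenosed vessel,
and the wall-shear index chain used to characterize arterial blockage
growth: **TAWSS → OSI → RRT**.

## The problem

As an arterial stenosis develops, the lumen narrows and the local
hemodynamics change long before the blockage is clinically obvious.
Three wall-shear-derived indices summarize one cardiac cycle of the wall
shear stress (WSS) vector τ⃗_w:

* **TAWSS** `= (1/T)∫₀ᵀ|τ⃗_w|dt` — time-averaged WSS magnitude (Pa); low
  values mark atherosclerosis-prone endothelium.
* **OSI** `= ½(1 − |∫₀ᵀτ⃗_w dt| / ∫₀ᵀ|τ⃗_w|dt)` — oscillatory shear index,
  0 for a direction-constant WSS vector, 0.5 for purely oscillatory flow.
* **RRT** `= 1/((1 − 2·OSI)·TAWSS)` — relative residence time (Pa⁻¹), a
  proxy for how long blood elements linger near the wall; singular where
  OSI → 0.5.

`stenoflow` computes these from first principles for a family of
axisymmetric vessels whose throat cross-section area is reduced by a
severity fraction S ∈ {0, 25, 35, 50, 65 %}: an incompressible
Navier–Stokes solver (finite volume, BDF2 in time, incremental pressure
projection) with Carreau-Yasuda shear-thinning viscosity

    μ(γ̇) = μ∞ + (μ₀ − μ∞)/(1 + (λγ̇)²)^((1−n)/2),

pulsatile inlet-velocity / outlet-pressure boundary waveforms at
70 bpm, rigid no-slip walls, and analytic Poiseuille/Womersley oracles
for validation. See `docs/methods.md` for the model, discretization and
design choices.

This is a desk-scale research and teaching artifact for cross-severity
*trends*, not a patient-specific simulator: the geometry is a straight
axisymmetric tube with a smooth cosine bump, and the boundary waveforms
are parametric emulations of clinical recordings.

## Worked example

Run the default five-severity sweep (healthy + 25/35/50/65 % area
reduction, identical waveforms and grid) from Python:

```python
import stenoflow as sf
report = sf.run_severity_sweep(sf.default_config(), out_dir="sweep_out")
print(report.table.to_string(index=False))
```

or from the shell: `stenoflow sweep --out sweep_out`. Each severity runs
about half a minute; the printed report is

```
 severity  peak_throat_velocity_m_per_s  amplification  p_systolic_mmHg  p_mid_diastolic_mmHg  p_end_diastolic_mmHg  tawss_max_Pa  osi_max  rrt_max_inv_Pa  rrt_median_inv_Pa  rrt_min_inv_Pa  rrt_flagged  periodicity_residual
     0.00                      0.499181       1.000000       119.854963             80.021900             79.999624      9.773739 0.456349        1.256936           1.233086        1.154507            0              0.000012
     0.25                      0.665574       1.333333       119.857597             80.021904             79.999628     42.281635 0.494349        5.081316           1.246369        0.377028            0              0.000033
     0.35                      0.767970       1.538462       119.854114             80.021911             79.999635     80.726933 0.498816       17.401317           1.251121        0.241428            0              0.000043
     0.50                      0.998361       2.000000       119.836253             80.021923             79.999647    205.895116 0.499161       46.686024           1.259229        0.102077            0              0.000055
     0.65                      1.426231       2.857143       119.826855             80.021808             79.999533    554.769253 0.499735       38.572735           1.233338        0.033155            1              0.000122
```

Reading the table:

* `peak_throat_velocity` is the peak cross-section-mean velocity at the
  throat; `amplification` is its ratio to the healthy run. Because the
  inlet volume flow is identical across runs and the solver conserves
  mass to ~10⁻¹³, the amplification follows the continuity estimate
  1/(1 − S): below 2 for blockages under 50 % and ≥ 2 beyond — a 65 %
  blockage nearly triples the throat velocity.
* `tawss_max` grows steeply with severity (9.8 → 555 Pa) and peaks at
  the throat, while `osi_max` approaches its 0.5 ceiling as the
  post-stenotic flow becomes fully oscillatory.
* `rrt_max` rises with severity until positions reach the OSI = 0.5
  singularity of the RRT definition; those are flagged (`rrt_flagged`)
  and capped rather than reported as infinities.
* `periodicity_residual` is the cycle-to-cycle L2 difference of the
  velocity field (~10⁻⁴: the final cycle is effectively periodic).
* The pressure extrema are pinned by the imposed outlet waveform in this
  single-outlet geometry and barely move with severity (see
  `docs/methods.md`, Known limitations).

Per-severity probe waveforms (`probes_*.csv`), wall-index profiles
(`indices_*.csv`), a `run.log` and the `report.csv` above are written to
the output directory. Wall indices can also be computed directly from
any wall-traction table:

```
stenoflow indices --traction traction.csv --out indices.csv
```

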