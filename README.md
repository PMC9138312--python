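# fibrilfrag

Amyloid fibrils — the filamentous protein polymers behind synucleinopathies
and other protein-misfolding diseases — multiply by breaking: every
fragmentation event creates new fibril ends and new seeds. How easily a
fibril breaks depends on its length and on its structural polymorph, so the
*fragmentation stability* of a fibril type is a quantitative, comparable
property. `fibrilfrag` implements the complete analysis used to measure it
from AFM imaging of sonicated fibril samples:

1. **Simulate** a fibril population fragmenting under mechanical
   perturbation. Each fibril of length *x* (nm) breaks with hazard
   **B(x) = (α·x)^γ s⁻¹** into two fragments; total length is conserved
   and heights (polymorph labels) pass unchanged to fragments. An exact
   event-driven Monte-Carlo simulator and a deterministic fixed-pivot
   population-balance solver cross-validate each other.
2. **Render** populations as synthetic AFM height maps (2048² px over
   10×10 µm by default): worm-like-chain deposition on a mica-like field,
   Gaussian ridge cross-sections, per-scan-line tilt, frame bow, and pixel
   noise. Real AFM images (float TIFF or plain matrix text) enter the
   pipeline at the next stage the same way.
3. **Quantify**: two-pass per-line flattening, thresholding,
   skeleton tracing of individual particles (crossings and edge-touching
   particles flagged and excluded), digital straightening, and
   edge-exclusion bias correction, yielding normalised length
   distributions *f(t, x)* and height distributions per sonication time.
4. **Infer** the rate law. The mean length follows
   **μ(t) = C·t^(−1/γ)** past a plateau time *t*ₛ, giving γ from a
   log–log fit; the rate scale follows from the γ-moment of each
   post-plateau distribution, **α_t = (γ·t·∫x^γ f(t,x) dx)^(−1/γ)**,
   averaged over time points. Standard errors are delete-one jackknife
   over time points. Fitted laws for different fibril types are compared
   through their B(x) curves (e.g. B₁₀₀ ≡ B(100 nm)).

## Worked example

Simulate a sonication time course with known truth, then fit it back:

```bash
fibrilfrag simulate --gamma 2.7 --alpha 9.1e-4 --n-fibrils 2000 \
    --median-length 800 --seed 1 --out pops.csv
# pops.csv is a tidy table (time_s, fibril_id, length_nm, height_nm, ...);
# rename its columns to the measurement schema and add unit weights:
python -c "import pandas as pd; df = pd.read_csv('pops.csv').rename(columns={
    'length_nm': 'contour_length_nm', 'height_nm': 'mean_height_nm'});
df['weight'] = 1.0; df.to_csv('measured.csv', index=False)"
fibrilfrag fit --traced measured.csv --name WT --out fit.json
```

prints

```
8 snapshots -> pops.csv
gamma=2.662+-0.0044 alpha=0.0008887 t_s=0 B100=0.001589/s -> fit.json
```

i.e. the fit recovers the simulation truth (γ = 2.7, α = 9.1·10⁻⁴ nm⁻¹)
within a few percent, and the implied division rate for a 100 nm fibril
is ≈1.5·10⁻³ s⁻¹ — such a fibril breaks about once every 11 minutes under
this perturbation, while a 1000 nm fibril of the same type breaks about
every 1.3 s. Higher γ means the rates fall much faster as fibrils shorten,
which is why strongly length-dependent types stop fragmenting earlier and
plateau at longer mean lengths.

Full runs (simulate → render → quantify → fit → compare, with every
intermediate persisted and resumable) are driven by a YAML config:

```bash
fibrilfrag run -c config.yaml
fibrilfrag figures --report out/report.json --outdir figs
```

See `fibrilfrag run --help` and `RunConfig` for the schema; set
`imaging: false` to skip the image stages and fit populations directly.

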