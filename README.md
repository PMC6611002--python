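# steftr

Behavioral-state estimation and comprehensive feature extraction from animal
movement trajectories — worms on an agar plate, penguins carrying GPS
loggers, tethered flies on a trackball, bats flying through an obstacle
course. The package is for ethologists, movement ecologists and
neuroscientists who have nothing but time-stamped coordinates and want (a)
an unsupervised segmentation of each track into behavioral states and (b) a
transparent ranking of which behavioral features distinguish two
experimental conditions.

## The method

**State estimation.** From each trajectory, resampled to a time unit of
roughly 1/1000 of the median recording duration, four primitive streams are
computed: velocity *V*, bearing *B*, and their per-frame differentials *dV*
and *dB* (wrapped into (−180°, 180°]). A centered moving average and moving
variance over a window of roughly 1/100 of the recording duration turn these
into eight basic features (*V_Ave* … *dB_Var*). Each pooled feature
histogram is modeled as a 1-D Gaussian mixture

    p(f | M_N) = Σₙ πₙ 𝒩(f; μₙ, σₙ),

fitted by EM; the cluster number *N* grows from 1 and stops when 10-fold
cross-validated held-out likelihood stops improving significantly. Each
histogram is scored by the separation index

    s(H) = (1 − Ov(M_N)) + min(N, Mx(H)) / N,

where *Ov* is the overlapping area of adjacent weighted components and *Mx*
counts visible density peaks (kernel density estimate; maxima below 0.1% of
the peak are noise). The best-scoring feature with at least two
location-separated clusters defines the states: every frame gets the
maximum-posterior component label, labels are smoothed by a sliding majority
vote, and cluster 0 is always the component with the smallest mean.

**Feature extraction.** For two-condition comparisons, every column of a
per-segment feature table (for worms: 333 features per cluster-0 segment —
{V, dV, B, dB, C, dC} × {Ave, Med} × {Ini, Mid, Ter, All} × 1–6 s windows,
a directedness block, the weathervane index and bout durations) is evaluated
as a decision stump: the threshold maximizing the information gain

    H = − Σₙ pₙ log₂ pₙ,   gain = H(parent) − Σ weighted H(children)

is found exhaustively, and features whose best split passes the
Fayyad–Irani MDL acceptance rule are reported as *extracted*.

A synthetic state-switching random-walk generator with exponential bout
durations provides ground truth for every stage.

## Worked example

```sh
python examples/01_simulate_and_estimate_states.py
```

simulates 20 worm-like animals (runs: 30 s mean, 10° heading noise;
pirouettes: 5 s mean, frequent >90° turns), estimates states without seeing
the truth, and prints:

```
selected feature : dB_Var
cluster number   : 5
separation scores:
  V_Ave   N=1 Ov=0.000 Mx=1 s=2.000
  dV_Ave  N=1 Ov=0.000 Mx=1 s=2.000
  dB_Ave  N=2 Ov=0.071 Mx=4 s=1.929
  B_Ave   N=5 Ov=0.152 Mx=2 s=1.248
  dB_Var  N=5 Ov=0.170 Mx=2 s=1.230
  B_Var   N=5 Ov=0.173 Mx=2 s=1.227
  dV_Var  N=5 Ov=0.265 Mx=2 s=1.135
  V_Var   N=4 Ov=0.257 Mx=1 s=0.993
run sensitivity      : 0.915
false positive rate  : 0.059
```

The turning-noise feature *dB_Var* wins (single-cluster features and
non-separated candidates cannot compete; see `docs/methods.md`), and the
two-way grouped labels recover 91% of run frames while mislabeling 5% of
pirouette frames. The other examples cover information-gain extraction
(`02`), the classic turn-interval t_crit classifier (`03`) and bat
obstacle-passage features (`04`).

A thin CLI wraps the same calls:

```sh
steftr simulate --out traj.csv --truth truth.csv --seed 1
steftr estimate --input traj.csv --out labels.csv --report scores.tsv
steftr evaluate --pred labels.csv --truth truth.csv
steftr extract --features table.csv --condition-col cond --out report.tsv
```

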