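# phikit

Integrated-information (IIT 3.0) causal analysis for discrete Markovian
dynamical systems of binary elements.

Given a network of interacting binary nodes — specified by its transition
probability matrix (TPM) and, optionally, a connectivity matrix — `phikit`
unfolds the system's full **cause-effect structure (CES)**:

* **cause/effect repertoires** — interventional conditional distributions
  Pr(P<sub>t−1</sub> | M<sub>t</sub> = m) and Pr(P<sub>t+1</sub> | M<sub>t</sub> = m)
  describing how a *mechanism* M in its current state constrains a *purview*
  P of the system, computed from the TPM by conditioning and uniform
  marginalization, with independent ("virtual-node") noise per input;
* **φ (small phi)** — the irreducibility of a mechanism-purview pair: the
  earth mover's distance (Hamming ground metric) between its repertoire and
  the closest factored repertoire over all bipartitions (the
  minimum-information partition, MIP);
* **concepts** — a mechanism's maximally-irreducible cause (MIC) and effect
  (MIE) over all purviews, with φ = min(φ_cause, φ_effect);
* **Φ (big phi)** — the irreducibility of the whole CES: the minimal
  extended-EMD distance between the CES and the CES recomputed under any
  unidirectional system cut;
* **complexes** — the subsystems where Φ is maximal.

The intended users are researchers studying integration, differentiation and
emergence in Boolean network models (gene regulatory circuits, neural
micro-circuits, cellular automata) who need exact Φ values and the
intermediate causal quantities, not just a single summary number.

## Worked example

The canonical demonstration system has three deterministic gates,
A = OR(B, C), B = AND(A, C), C = XOR(A, B), no self-connections, analyzed in
state (A, B, C) = (1, 0, 0):

```python
>>> import phikit as pk
>>> net = pk.example_network()
>>> sub = pk.Subsystem(net, (1, 0, 0))

>>> pk.cause_repertoire(sub, (0,), (0, 1, 2)).flatten()
array([0.        , 0.        , 0.16666667, 0.16666667, 0.16666667,
       0.16666667, 0.16666667, 0.16666667])
```

A being ON rules out every past state in which B and C were both OFF — the
two zeros are states (0,0,0) and (1,0,0) (little-endian: the first node is
the least-significant bit).

```python
>>> ria = pk.effect_mip(sub, (0, 1, 2), (0, 1, 2))
>>> ria.phi, str(ria.partition)
(0.25, '[∅/1 x 0,1,2/0,2]')
```

The effect of the whole mechanism ABC over ABC cannot be factored into
(ABC over AC) × (∅ over B) without information loss: φ = 0.25.

```python
>>> analysis = pk.sia(sub)
>>> analysis.phi, analysis.cut
(1.916666, SystemCut(from_part=(0, 1), to_part=(2,)))
>>> [c.mechanism for c in analysis.ces]
[(0,), (1,), (2,), (0, 1), (1, 2), (0, 1, 2)]
```

Every mechanism except AC specifies a concept; the minimal system cut severs
the connections from {A, B} into {C}, and Φ ≈ 1.92. The same analysis is
available from the shell:

```sh
phikit analyze sia example --state 1,0,0
phikit analyze concept example --state 1,0,0 --mechanism B,C
phikit fixtures make --kind noisy_majority_chain --n 5 --noise 0.1 --out chain.json
```

## Configuration

`pk.Config` / `pk.load_config` control the analysis: distance measures
(registries; EMD and extended-EMD ship), the partition scheme
(bipartitions), the `cut_one` and `no_new_concepts` approximations,
φ-rounding precision (6 decimals), and optional parallel cut evaluation. A
`phikit_config.yml` in the working directory is auto-discovered (opt-out
with `--no-auto-config` on the CLI). Defaults reproduce the worked example
above.
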