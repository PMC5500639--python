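"""The five canonical network architectures and their shape algebra.

Prints each architecture's layer stack with the propagated output volume
at every layer, plus the closed-form trainable-parameter count.
"""

from phenonet import canonical_spec, count_parameters
from phenonet.architectures import TASK_IDS
from phenonet.nn import output_shape

for task_id in TASK_IDS:
    spec = canonical_spec(task_id)
    print(f"\n{spec.name}: input {spec.input_size[0]}x{spec.input_size[1]}x3, "
          f"train crop {spec.train_input_size[0]}x{spec.train_input_size[1]}, task {spec.task}")
    shape = (*spec.train_input_size, 3)
    for layer in spec.layers:
        shape = output_shape(layer, shape)
        print(f"   {layer.kind:16s} -> {shape}")
    print(f"   trainable parameters: {count_parameters(spec):,}")

print(
    "\nSame-padded stride-1 convolutions keep the spatial size; each 3x3\n"
    "stride-2 max pool halves it (with ceiling).  The mutant classifier\n"
    "ends in softmax over 5 classes; all regressors end in a single\n"
    "linear output unit."
)
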