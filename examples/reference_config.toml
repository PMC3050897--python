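# Reference configuration: every key with its default value.
#
# Network parameters live in the [network] table; protocol keys at the
# top level are picked up by the CLI subcommands and by run_curriculum.

# --- protocol -------------------------------------------------------
T_stab = 600.0        # contiguous time below eps_d required for success
T_max = 40000.0       # per-step timeout
K = 20                # random initial states per memorization test
bs_stab_scale = 0.02  # backward plasticity during stabilization
                      # (0 = frozen, 1 = fully plastic)

[network]
N = 16                # neurons per layer
tau = 1.0             # neural time constant (all times in units of tau)
beta = 100.0          # activation gain
# theta defaults to log(1/r0 - 1)/beta so that activation(0) = r0
c_inh = -1.0          # intralayer inhibition strength
gamma_learn = 2.0     # input strength during learning and recall
dt = 0.01             # explicit-Euler step
r0 = 0.1              # spontaneous firing rate
eps_d = 0.5           # Hebbian/anti-Hebbian switching threshold
lambda_penalty = 0.1  # anti-Hebbian (penalty) learning-rate factor
tau_f = 100.0         # forward-synapse plasticity timescale
tau_b = 10.0          # backward-synapse plasticity timescale
w_max = "inf"         # synaptic upper bound (finite for the overlap task)
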