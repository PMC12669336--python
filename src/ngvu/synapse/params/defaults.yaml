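# Parameter registry for the quadripartite synapse (0D cellular scale).
# Every entry: value, units, source in {paper, literature, calibrated}.
# "calibrated" entries are recomputed at startup so that the resting state
# is a fixed point; the stored value is the fallback.

# --- presynaptic Hodgkin-Huxley membrane (resting potential -70 mV) ---
hh_C:      {value: 1.0,    units: uF/cm^2,  source: literature}
hh_gK:     {value: 36.0,   units: mS/cm^2,  source: literature}
hh_gNa:    {value: 120.0,  units: mS/cm^2,  source: literature}
hh_gL:     {value: 0.3,    units: mS/cm^2,  source: literature}
hh_VK:     {value: -82.0,  units: mV,       source: literature}
hh_VNa:    {value: 45.0,   units: mV,       source: literature}
hh_VL:     {value: -59.387, units: mV,      source: literature}
hh_Iapp:   {value: 10.0,   units: uA/cm^2,  source: calibrated}

# --- bouton geometry and N-type channel ---
A_btn:     {value: 1.24,   units: um^2,     source: literature}
V_btn:     {value: 0.13,   units: um^3,     source: literature}
z_Ca:      {value: 2.0,    units: '-',      source: paper}
temperature: {value: 310.0, units: K,       source: literature}
c_ext:     {value: 2000.0, units: uM,       source: literature}
c_i_rest:  {value: 0.1,    units: uM,       source: literature}
rho_Ca:    {value: 20.0,    units: um^-2,    source: calibrated}
g_Ca:      {value: 2.3,    units: pS,       source: literature}
V_mCa:     {value: -17.0,  units: mV,       source: literature}
k_mCa:     {value: 8.4,    units: mV,       source: literature}
tau_mCa:   {value: 1.0,    units: ms,       source: literature}

# --- plasma-membrane pump/leak (fast calcium) ---
K_PM_Ca:   {value: 3.0,    units: uM,       source: literature}
v_PM_Ca:   {value: 0.0,    units: fA/um^2,  source: calibrated}
v_leak:    {value: 0.011,   units: 1/s,      source: calibrated}
buffer_kappa: {value: 20.0, units: '-',     source: literature}

# --- bouton slow calcium (adapted Li-Rinzel with dynamic ER) ---
c1_ratio:  {value: 0.1,    units: '-',      source: calibrated}
c_ER_rest: {value: 150.0,  units: uM,       source: literature}
v1:        {value: 1.0,    units: 1/s,      source: calibrated}
v2:        {value: 0.01,   units: 1/s,      source: calibrated}
v3:        {value: 0.9,    units: uM/s,     source: literature}
k3:        {value: 0.05,    units: uM,       source: literature}
d1:        {value: 0.13,   units: uM,       source: literature}
d2:        {value: 1.049,  units: uM,       source: literature}
d3:        {value: 0.9434, units: uM,       source: literature}
d5:        {value: 0.08234, units: uM,      source: literature}
a2:        {value: 0.2,    units: 1/(uM s), source: literature}
v_g:       {value: 0.5,    units: uM/s,     source: literature}
k_g:       {value: 1.0,    units: uM,       source: literature}
tau_p:     {value: 0.14,   units: 1/s,      source: literature}  # rate, see registry note
p0:        {value: 0.16,   units: uM,       source: literature}

# --- vesicle sensor kinetics (five binding sites + isomerization) ---
sensor_alpha: {value: 0.3,  units: 1/(uM ms), source: literature}
sensor_beta:  {value: 3.0,  units: 1/ms,      source: literature}
sensor_gamma: {value: 30.0, units: 1/ms,      source: literature}
sensor_delta: {value: 8.0,  units: 1/ms,      source: literature}
n_docked:     {value: 2,    units: '-',       source: literature}

# --- spontaneous release (Poisson) ---
spont_a1:  {value: 5.0,    units: uM,       source: calibrated}
spont_a2:  {value: 1.0,    units: uM,       source: calibrated}
spont_a3:  {value: 3.0,    units: 1/s,      source: literature}

# --- Tsodyks-Markram vesicle pools ---
tau_rec:     {value: 0.8,   units: s,   source: literature}
tau_inact:   {value: 0.003, units: s,   source: literature}
refractory_glu:  {value: 0.00634, units: s, source: paper}
refractory_gaba: {value: 0.0072,  units: s, source: paper}
u_release:   {value: 0.5,   units: '-', source: calibrated}

# --- cleft / extrasynaptic transmitter ---
n_v:       {value: 10.0,   units: '-',      source: literature}
g_v_glu:   {value: 60000.0, units: uM,      source: paper}      # 60 mM
g_v_gaba:  {value: 20000.0, units: uM,      source: paper}      # 20 mM
g_c:       {value: 1000.0, units: 1/s,      source: literature}
n_a_v:     {value: 2.0,    units: '-',      source: literature}
g_a_v:     {value: 60000.0, units: uM,      source: paper}
g_a_c:     {value: 1000.0, units: 1/s,      source: literature}

# --- astrocyte G-ChI ---
r_Ca:      {value: 6.0,    units: 1/s,      source: literature}
v_ER:      {value: 0.9,    units: uM/s,     source: literature}
K_ER:      {value: 0.1,    units: uM,       source: literature}
r_L:       {value: 0.11,   units: 1/s,      source: literature}
c0_astro:  {value: 2.0,    units: uM,       source: literature}
c1_astro:  {value: 0.185,  units: '-',      source: literature}
v_beta:    {value: 0.2,    units: uM/s,     source: literature}
K_R:       {value: 1.3,    units: uM,       source: literature}
K_p:       {value: 10.0,   units: uM,       source: literature}
K_pi:      {value: 0.6,    units: uM,       source: literature}
v_delta:   {value: 0.02,   units: uM/s,     source: literature}
k_delta:   {value: 1.5,    units: uM,       source: literature}
K_PLCdelta: {value: 0.1,   units: uM,       source: literature}
v_3K:      {value: 2.0,    units: uM/s,     source: literature}
K_D:       {value: 0.7,    units: uM,       source: literature}
K_3:       {value: 1.0,    units: uM,       source: literature}
r_5Pa:     {value: 0.04,   units: 1/s,      source: literature}
N_IP3:     {value: 20,     units: '-',      source: literature}

# --- gliotransmitter release gates and pools ---
gate_Kd1:  {value: 0.108,  units: uM,       source: paper}
gate_Kd2:  {value: 0.4,    units: uM,       source: paper}
gate_Kd3:  {value: 0.8,    units: uM,       source: paper}
gate_tau1: {value: 2.5,    units: s,        source: paper}
gate_tau2: {value: 1.0,    units: s,        source: paper}
gate_tau3: {value: 0.1,    units: s,        source: paper}
c_a_thresh: {value: 0.2,   units: uM,       source: literature}
tau_rec_a:  {value: 0.8,   units: s,        source: literature}
tau_inact_a: {value: 3.0,  units: s,        source: literature}

# --- postsynaptic passive membrane (PSP read-out) ---
psp_C:       {value: 1.0,  units: uF/cm^2,  source: literature}
psp_gL:      {value: 0.1,  units: mS/cm^2,  source: calibrated}
psp_Vrest:   {value: -70.0, units: mV,      source: literature}
psp_gAMPA:   {value: 0.05, units: mS/cm^2,  source: calibrated}
psp_gNMDA:   {value: 0.012, units: mS/cm^2,  source: calibrated}
psp_gGABA:   {value: 0.04, units: mS/cm^2,  source: calibrated}
psp_K_AMPA:  {value: 3.0,  units: uM,       source: calibrated}
psp_K_GABA:  {value: 3.0,  units: uM,       source: calibrated}
psp_V_E:     {value: 0.0,  units: mV,       source: literature}
psp_V_I:     {value: -80.0, units: mV,      source: literature}
K_m_A:       {value: 40.0, units: uM,       source: literature}
K_m_B:       {value: 12.0, units: uM,       source: literature}
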