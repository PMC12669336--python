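# Parameter registry for the neurovascular coupling / vessel wall module.
# source in {paper, literature, calibrated}; "calibrated" values were fitted
# so the default coupled system rests at a physiological operating point.

# --- KIR channel (linear fit of the Nernst-like potential) ---
F_KIR:     {value: 1.0,    units: '-',      source: literature}
g_KIR:     {value: 0.2,    units: 1/s,      source: calibrated}
gamma_conv: {value: 1.0,   units: '-',      source: literature}
z1:        {value: 4.5,    units: mV/mM,    source: literature}
z2:        {value: 112.0,  units: mV,       source: literature}
K_p_rest:  {value: 3.5,    units: mM,       source: literature}

# --- heterocellular gap-junction coupling ---
P_Ca:      {value: 0.05,   units: 1/s,      source: literature}
G_v:       {value: 1.0,    units: 1/s,      source: literature}
P_IP3:     {value: 0.05,   units: 1/s,      source: literature}

# --- SMC / EC compartments (reduced Koenigsberger-style system) ---
free_ca_fraction: {value: 0.01, units: '-', source: paper}   # ~1% free
k_ext_i:   {value: 30.0,   units: 1/s,      source: calibrated}
k_ext_j:   {value: 20.0,   units: 1/s,      source: calibrated}
J0_i:      {value: 4.0,    units: uM/s,     source: calibrated}
J0_j:      {value: 3.0,    units: uM/s,     source: calibrated}
g_VOCC:    {value: 10.0,   units: uM/s,     source: calibrated}
v_VOCC_half: {value: -35.0, units: mV,      source: literature}
v_VOCC_slope: {value: 9.0, units: mV,       source: literature}
k_ip3_rel: {value: 60.0,   units: 1/s,      source: calibrated}
K_ip3_i:   {value: 0.6,    units: uM,       source: literature}
k_sr_leak: {value: 0.2,    units: 1/s,      source: calibrated}
B_i:       {value: 2.0,    units: uM/s,     source: literature}
c_bi:      {value: 0.5,    units: uM,       source: literature}
J_EC_IP3:  {value: 0.3,    units: uM/s,     source: literature}
k_deg_ip3_i: {value: 0.5,  units: 1/s,      source: literature}
k_deg_ip3_j: {value: 0.5,  units: 1/s,      source: literature}
g_L_v_i:   {value: 1.0,    units: 1/s,      source: calibrated}
v_L_i:     {value: -40.0,  units: mV,       source: literature}
g_L_v_j:   {value: 1.0,    units: 1/s,      source: calibrated}
v_L_j:     {value: -45.0,  units: mV,       source: literature}
g_BK:      {value: 2.0,    units: 1/s,      source: calibrated}
v_K_rev:   {value: -90.0,  units: mV,       source: literature}
v_BK_half: {value: -25.0,  units: mV,       source: literature}
v_BK_slope: {value: 15.0,  units: mV,       source: literature}
lambda_BK: {value: 30.0,   units: mV,       source: calibrated}

# --- Hai-Murphy cross-bridge kinetics ---
K2:        {value: 0.5,    units: 1/s,      source: literature}
K3:        {value: 0.4,    units: 1/s,      source: literature}
K4:        {value: 0.1,    units: 1/s,      source: literature}
K5:        {value: 0.5,    units: 1/s,      source: literature}
K7:        {value: 0.1,    units: 1/s,      source: literature}
gamma_cross: {value: 17.0, units: 1/(uM^3 s), source: literature}
K_m_mlcp:  {value: 2.0,    units: uM,       source: literature}
k_mlpc_b:  {value: 0.0086, units: 1/s,      source: literature}
k_mlpc_c:  {value: 0.0327, units: 1/s,      source: literature}
delta_i:   {value: 20.0,   units: '-',      source: calibrated}

# --- Kelvin-Voigt wall mechanics ---
dp_wall:   {value: 4000.0, units: Pa,       source: literature}  # ~30 mmHg
eta_wall:  {value: 100000.0,  units: Pa s,     source: calibrated}
E_pas:     {value: 30000.0, units: Pa,       source: calibrated}
E_act:     {value: 233000.0, units: Pa,      source: literature}
R0_pas:    {value: 20.0,   units: um,       source: literature}
R0_act:    {value: 12.0,   units: um,       source: literature}

# --- NO pathway ---
V_max_NO_n: {value: 1.0,   units: uM/s,     source: literature}
O2_n:      {value: 200.0,  units: uM,       source: literature}
K_m_O2_n:  {value: 240.0,  units: uM,       source: literature}
LArg_n:    {value: 100.0,  units: uM,       source: literature}
K_m_LArg_n: {value: 1.5,   units: uM,       source: literature}
V_max_NO_j: {value: 1.2,   units: uM/s,     source: literature}
O2_j:      {value: 200.0,  units: uM,       source: literature}
K_m_O2_j:  {value: 240.0,  units: uM,       source: literature}
LArg_j:    {value: 100.0,  units: uM,       source: literature}
K_m_LArg_j: {value: 1.5,   units: uM,       source: literature}
K_m_A:     {value: 40.0,   units: uM,       source: literature}
K_m_B:     {value: 12.0,   units: uM,       source: literature}
G_M:       {value: 46.0,   units: pS,       source: literature}
P_Ca_P_M:  {value: 3.6,    units: '-',      source: literature}
Ca_ex:     {value: 2000.0, units: uM,       source: literature}
M_mono:    {value: 150000.0, units: uM,     source: literature}
alpha_v:   {value: -0.08,  units: 1/mV,     source: literature}
beta_v:    {value: 20.0,   units: mV,       source: literature}
nNOS_max:  {value: 1.0,    units: uM,       source: calibrated}
K_act_nNOS: {value: 2.0,   units: pA,       source: calibrated}
tau_nNOS:  {value: 1.0,    units: s,        source: calibrated}
eNOS_ca_max: {value: 0.4,  units: uM,       source: calibrated}
K_eNOS_Ca: {value: 0.4,    units: uM,       source: literature}
eNOS_wss_max: {value: 0.4, units: uM,       source: calibrated}
K_wss:     {value: 1.0,    units: Pa,       source: literature}
tau_wss_default: {value: 1.0, units: Pa,    source: literature}
D_NO:      {value: 3300.0, units: um^2/s,   source: literature}
dx_na:     {value: 25.0,   units: um,       source: paper}
dx_as:     {value: 25.0,   units: um,       source: literature}
dx_se:     {value: 2.5,    units: um,       source: literature}
kC_n:      {value: 0.7,    units: 1/s,      source: literature}
kC_a:      {value: 0.7,    units: 1/s,      source: literature}
kC_s:      {value: 0.7,    units: 1/s,      source: literature}
kC_e:      {value: 1.0,    units: 1/s,      source: literature}

# --- cGMP / BK modulation ---
V_cGMP:    {value: 5.0,    units: uM/s,     source: calibrated}
K_NO_sGC:  {value: 0.1,    units: uM,       source: literature}
k_deg_cGMP: {value: 1.0,   units: 1/s,      source: calibrated}
eps_i:     {value: 0.5,    units: '-',      source: calibrated}
alpha_i:   {value: 0.5,    units: '-',      source: calibrated}
gamma_i:   {value: -0.5,   units: 1/uM,     source: calibrated}  # negative: cGMP opens BK
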