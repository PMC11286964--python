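variable,alpha,beta,extra_scale
m_protein,0.0,3.0,1.0
kappa_flc,3.3,19.4,0.2
lambda_flc,5.7,26.3,0.2
hemoglobin,120.0,160.0,1.0
creatinine,45.0,90.0,1.0
calcium,2.1,2.6,1.0
albumin,35.0,50.0,1.0
urate,155.0,428.0,0.2
upep_m_protein,0.0,150.0,0.2
iga,0.8,3.0,1.0
igg,6.0,16.0,1.0
igm,0.4,2.5,1.0
platelets,150.0,400.0,1.0
neutrophils,2.0,7.5,1.0
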