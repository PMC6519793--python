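baseline
tissue
sample
cohort
protocol
outcome
profile
pathway
receptor
signal
membrane
plasma
serum
marker
fraction
gradient
culture
medium
buffer
reagent
kinetics
threshold
variance
subset
cluster
domain
sequence
variant
isoform
substrate
enzyme
vesicle
nucleus
cytoplasm
mitochondria
ribosome
peptide
residue
helix
strand
motif
locus
allele
genome
transcript
translation
expression
regulation
modulation
distribution
localization
morphology
phenotype
viability
proliferation
differentiation
migration
adhesion
secretion
uptake
clearance
metabolism
homeostasis
equilibrium
stability
affinity
specificity
sensitivity
resolution
calibration
normalization
replicate
duplicate
aliquot
dilution
incubation
centrifugation
filtration
extraction
purification
elution
staining
imaging
microscopy
spectrometry
chromatography
electrophoresis
immunoblot
quantification
abundance
intensity
density
volume
diameter
interval
duration
frequency
amplitude
latency
onset
recovery
plateau
decline
elevation
reduction
accumulation
depletion
turnover
flux
transport
diffusion
permeability
conductance
potential
polarity
charge
viscosity
temperature
humidity
pressure
oxygenation
perfusion
circulation
vasculature
epithelium
endothelium
stroma
matrix
collagen
fibroblast
macrophage
lymphocyte
neutrophil
platelet
erythrocyte
hepatocyte
neuron
astrocyte
synapse
axon
dendrite
cortex
hippocampus
cerebellum
thalamus
ganglion
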