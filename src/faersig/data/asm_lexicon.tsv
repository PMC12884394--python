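synonym	canonical
carbamazepine	carbamazepine
tegretol	carbamazepine
carbatrol	carbamazepine
equetro	carbamazepine
epitol	carbamazepine
clonazepam	clonazepam
klonopin	clonazepam
rivotril	clonazepam
diazepam	diazepam
valium	diazepam
diastat	diazepam
lamotrigine	lamotrigine
lamictal	lamotrigine
levetiracetam	levetiracetam
keppra	levetiracetam
spritam	levetiracetam
oxcarbazepine	oxcarbazepine
trileptal	oxcarbazepine
oxtellar	oxcarbazepine
phenobarbital	phenobarbital
phenobarbitone	phenobarbital
phenobarbital sodium	phenobarbital
luminal	phenobarbital
phenytoin	phenytoin
phenytoin sodium	phenytoin
dilantin	phenytoin
phenytek	phenytoin
epanutin	phenytoin
topiramate	topiramate
topamax	topiramate
trokendi xr	topiramate
qudexy xr	topiramate
valproic acid	valproic acid
valproate	valproic acid
valproate sodium	valproic acid
sodium valproate	valproic acid
valproate semisodium	valproic acid
divalproex sodium	valproic acid
depakote	valproic acid
depakene	valproic acid
depacon	valproic acid
epilim	valproic acid
stavzor	valproic acid
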