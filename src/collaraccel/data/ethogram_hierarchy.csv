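fine,medium,coarse
crouch,sedentary,inactive
lie,sedentary,inactive
sit,sedentary,inactive
stand,sedentary,inactive
head movement,head movement,head movement
crouching stalk,crouching stalk,inactive
lying stalk,lying stalk,inactive
sitting stalk,sitting stalk,inactive
standing stalk,standing stalk,inactive
walking stalk,moving stalk,active
trotting stalk,moving stalk,active
walk,walk,active
trot,trot,active
canter,canter,active
gallop,gallop,active
pounce,other,active
other,other,other
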