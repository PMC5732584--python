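name,gender
anna,female
annabel,female
annabella,female
emma,female
olivia,female
sophie,female
sophia,female
amelia,female
isabella,female
isabelle,female
charlotte,female
grace,female
lucy,female
ella,female
ellie,female
chloe,female
lily,female
emily,female
hannah,female
megan,female
jessica,female
lauren,female
katie,female
kate,female
katherine,female
rebecca,female
rachel,female
sarah,female
laura,female
gemma,female
holly,female
abigail,female
bethany,female
eleanor,female
alice,female
rosie,female
rose,female
daisy,female
freya,female
imogen,female
maria,female
victoria,female
elizabeth,female
helen,female
claire,female
nicola,female
oliver,male
jack,male
harry,male
george,male
jacob,male
charlie,unisex
thomas,male
tom,male
oscar,male
william,male
liam,male
james,male
henry,male
leo,male
joshua,male
josh,male
freddie,male
archie,male
ethan,male
isaac,male
alexander,male
alex,unisex
joseph,male
joe,male
edward,male
samuel,male
sam,unisex
daniel,male
dan,male
arthur,male
max,male
benjamin,male
ben,male
mason,male
harrison,male
lucas,male
luke,male
michael,male
mike,male
adam,male
david,male
dave,male
matthew,male
matt,male
ryan,male
nathan,male
peter,male
pete,male
simon,male
andrew,male
andy,unisex
paul,male
mark,male
john,male
richard,male
robert,male
rob,male
chris,unisex
christopher,male
stephen,male
steve,male
kevin,male
gareth,male
owen,male
taylor,unisex
jordan,unisex
morgan,unisex
casey,unisex
jamie,unisex
robin,unisex
ashley,unisex
riley,unisex
frankie,unisex
billie,unisex
sidney,unisex
lee,unisex
kim,unisex
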